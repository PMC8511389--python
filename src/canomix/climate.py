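"""Synthetic daily climate series.

The simulator needs a daily sequence of mean air temperature (deg C) and incident
photosynthetically active radiation (PAR, mol m-2 d-1) from sowing to stand
maturity.  The generator emulates a smooth multi-site, multi-year average of
temperate (northern-French) conditions: a sinusoidal annual temperature cycle
with weak AR(1) noise, and a seasonal PAR curve with small multiplicative
noise, both anchored to a configurable sowing day of year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClimateConfig", "ClimateSeries", "generate_climate"]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the synthetic climate generator.

    Defaults emulate northern-French winter-wheat conditions: annual mean
    temperature 11 deg C with 8 deg C seasonal amplitude, sowing in late October
    (day of year 295), PAR peaking at 55 mol m-2 d-1 in midsummer with a
    winter trough of 5 mol m-2 d-1.  Noise terms are small because the
    emulated input is an average over many sites and years.
    """

    temp_annual_mean: float = 11.0  # deg C
    temp_amplitude: float = 8.0  # deg C, half peak-to-trough
    sowing_doy: int = 295  # day of year of sowing (late October)
    temp_noise_sd: float = 0.8  # deg C, innovation sd of the AR(1) noise
    temp_ar1: float = 0.7  # AR(1) coefficient of the temperature noise
    par_max: float = 55.0  # mol m-2 d-1 at the summer peak
    par_min: float = 5.0  # mol m-2 d-1 at the winter trough
    par_noise_sigma: float = 0.1  # sd of log multiplicative PAR noise
    temp_bounds: tuple[float, float] = (-15.0, 40.0)  # physical clamp, deg C
    # warmest day / highest sun around early July in the northern hemisphere
    peak_doy: int = 185


@dataclass(frozen=True)
class ClimateSeries:
    """Daily climate from sowing: day index, mean temperature, incident PAR."""

    day_index: np.ndarray  # integer days since sowing, 0-based
    temp_mean: np.ndarray  # deg C
    par_incident: np.ndarray  # mol m-2 d-1
    config: ClimateConfig = field(default_factory=ClimateConfig, compare=False)

    def __post_init__(self) -> None:
        n = len(self.day_index)
        if len(self.temp_mean) != n or len(self.par_incident) != n:
            raise ValueError("climate arrays must have equal length")
        if np.any(self.par_incident < 0):
            raise ValueError("par_incident must be non-negative")

    def __len__(self) -> int:
        return len(self.day_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day_index,
                "temp_c": self.temp_mean,
                "par_mol_m2_d": self.par_incident,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClimateSeries":
        return cls(
            day_index=df["day"].to_numpy(dtype=int),
            temp_mean=df["temp_c"].to_numpy(dtype=float),
            par_incident=df["par_mol_m2_d"].to_numpy(dtype=float),
        )


def generate_climate(
    n_days: int, seed: int, params: ClimateConfig | None = None
) -> ClimateSeries:
    """Generate a daily climate series of ``n_days`` starting at sowing.

    Deterministic for a fixed ``seed``.  Temperature is a sinusoidal annual
    cycle plus AR(1) noise, clamped to physical bounds; PAR is a seasonal
    sinusoid clipped at >= 0 with lognormal multiplicative noise.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    cfg = params if params is not None else ClimateConfig()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))

    days = np.arange(n_days)
    doy = (cfg.sowing_doy + days) % _DAYS_PER_YEAR
    phase = 2.0 * np.pi * (doy - cfg.peak_doy) / _DAYS_PER_YEAR

    temp = cfg.temp_annual_mean + cfg.temp_amplitude * np.cos(phase)
    if cfg.temp_noise_sd > 0:
        innov = rng.normal(0.0, cfg.temp_noise_sd, size=n_days)
        noise = np.empty(n_days)
        # stationary start so the series mean is unbiased
        noise[0] = innov[0] / np.sqrt(max(1.0 - cfg.temp_ar1**2, 1e-12))
        for t in range(1, n_days):
            noise[t] = cfg.temp_ar1 * noise[t - 1] + innov[t]
        temp = temp + noise
    temp = np.clip(temp, *cfg.temp_bounds)

    par_mid = 0.5 * (cfg.par_max + cfg.par_min)
    par_amp = 0.5 * (cfg.par_max - cfg.par_min)
    par = par_mid + par_amp * np.cos(phase)
    if cfg.par_noise_sigma > 0:
        par = par * rng.lognormal(0.0, cfg.par_noise_sigma, size=n_days)
    par = np.clip(par, 0.0, None)

    return ClimateSeries(day_index=days, temp_mean=temp, par_incident=par, config=cfg)
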