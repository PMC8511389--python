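"""Individual-based stand simulation with tillering plasticity.

The simulated plot is the repeating cell of an infinite periodic canopy:
plants sit on a grid, distances are minimum-image, and there are no border
effects.  Each day the simulator (a) advances development and morphology on
the thermal-time clock, (b) partitions the day's diffuse PAR among axes with
the layered turbid-medium light model, (c) applies the three tillering
rules — probabilistic emission of primary tillers, permanent cessation of
emission once the surrounding green area index (GAI) reaches the genotype
threshold GAI_c, and regression of tillers whose intercepted PAR per unit
green area per degree-day stays below the genotype threshold PAR_t — and
(d) records the dynamics.

Stand-level outputs: N_ears (mean surviving axes per plant at maturity;
every surviving axis bears one ear and there is no plant mortality, so
N_ears >= 1), L_perc (mean daily fraction of incident PAR intercepted from a
configurable start day to maturity) and F_tot (summed photothermal-quotient
fitness of all surviving axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import substream
from .canopy import Axis, DevConstants, Genotype, axis_profiles, thermal_time
from .climate import ClimateSeries
from .light import SkyDiscretization, diffuse_sky, partition_light

__all__ = [
    "Plant",
    "Plot",
    "SimulationConfig",
    "StandOutputs",
    "StandSimulator",
    "surrounding_gai",
    "simulate_stand",
]

_ACTIVE, _REGRESSING, _REGRESSED = 0, 1, 2


@dataclass
class Plant:
    """One plant of the stand."""

    position: tuple[float, float]  # (x, y) in m within the periodic cell
    genotype_id: int
    axes: list[Axis] = field(default_factory=list)
    emergence_delay_tt: float = 0.0  # random pre-emergence duration, deg Cd

    def __post_init__(self) -> None:
        ranks = [a.rank for a in self.axes]
        if len(ranks) != len(set(ranks)):
            raise ValueError("axis ranks must be unique within a plant")


@dataclass
class Plot:
    """Periodic plot: plants, genotype table, density and cell size."""

    plants: list[Plant]
    genotypes: list[Genotype]
    density: float  # plants m-2
    domain: tuple[float, float]  # (width, height) m of the periodic cell
    layer_dz: float = 2.0  # light-model layer thickness, cm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        area = self.domain[0] * self.domain[1]
        if abs(len(self.plants) / area - self.density) > 0.01 * self.density:
            raise ValueError("plant count, domain and density are inconsistent")
        for p in self.plants:
            if not (0 <= p.genotype_id < len(self.genotypes)):
                raise ValueError(f"unknown genotype_id {p.genotype_id}")

    def __iter__(self):
        return iter(self.plants)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def ground_area(self) -> float:
        return self.domain[0] * self.domain[1]


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable stand-simulation settings (see the methods note for rationale)."""

    t_base: float = 0.0  # deg C, base temperature of the thermal clock
    n_sky_directions: int = 16
    gai_radius: float = 0.15  # m, neighborhood disc for the cessation rule
    whole_plot_gai: bool = False  # use plot-level GAI instead of the disc
    regression_window: int = 7  # days of the running-mean PAR-per-area test
    regression_decay_days: int = 5  # linear green-area decay once regressing
    l_perc_start_day: int = 100  # days after sowing; start of the average
    emergence_delay_range: tuple[float, float] = (80.0, 150.0)  # deg Cd


@dataclass
class StandOutputs:
    """Stand-level results of one simulation."""

    n_ears: float  # mean surviving axes (= ears) per plant at maturity
    l_perc: float  # mean intercepted fraction of incident PAR
    f_tot: float  # total plot fitness, mol degCd-1
    tillering_dynamics: np.ndarray  # (n_days, n_plants) live axis counts
    interception_dynamics: np.ndarray  # (n_days,) daily intercepted fraction
    maturity_day: int = -1

    def __post_init__(self) -> None:
        if self.n_ears < 1.0:
            raise ValueError("n_ears must be >= 1 (no plant mortality)")
        if not (0.0 <= self.l_perc <= 1.0):
            raise ValueError("l_perc must lie in [0, 1]")
        if self.f_tot < 0.0:
            raise ValueError("f_tot must be >= 0")


def _min_image(delta: np.ndarray, span: float) -> np.ndarray:
    return delta - span * np.round(delta / span)


def periodic_distances(positions: np.ndarray, domain: tuple[float, float]) -> np.ndarray:
    """Pairwise minimum-image distances on the periodic cell."""
    dx = _min_image(positions[:, None, 0] - positions[None, :, 0], domain[0])
    dy = _min_image(positions[:, None, 1] - positions[None, :, 1], domain[1])
    return np.hypot(dx, dy)


def surrounding_gai(plot: Plot, plant: Plant | int, radius: float) -> float:
    """Green area index of the disc around a focal plant.

    Sums the green area (cm2 -> m2) of every axis of plants whose periodic
    (minimum-image) distance to the focal plant is <= radius, including the
    focal plant itself, and divides by the disc area pi r^2.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    half_diag = 0.5 * float(np.hypot(*plot.domain))
    if radius > half_diag:
        raise ValueError(
            "radius exceeds half the domain diagonal; periodic images ambiguous"
        )
    idx = plot.plants.index(plant) if isinstance(plant, Plant) else int(plant)
    positions = np.array([p.position for p in plot.plants])
    d = periodic_distances(positions, plot.domain)[idx]
    total_cm2 = 0.0
    for j, p in enumerate(plot.plants):
        if d[j] <= radius:
            for ax in p.axes:
                if ax.green_area_by_layer is not None and ax.status != "regressed":
                    total_cm2 += float(np.sum(ax.green_area_by_layer))
    return total_cm2 * 1e-4 / (np.pi * radius**2)


class StandSimulator:
    """Daily-step engine over a :class:`Plot` and a climate series.

    All randomness (emergence delays, tiller-emission draws) is derived from
    one master seed via named substreams, keyed by plant index only — so two
    plots that differ solely in genotype labels share their random draws,
    which makes seed-matched overyielding comparisons exact.
    """

    def __init__(
        self,
        plot: Plot,
        climate: ClimateSeries,
        config: SimulationConfig | None = None,
        seed: int | None = None,
    ) -> None:
        self.plot = plot
        self.climate = climate
        self.config = config or SimulationConfig()
        self.seed = plot.rng_seed if seed is None else int(seed)

        if len({g.dev for g in plot.genotypes}) > 1:
            raise ValueError("all genotypes in a plot must share dev constants")
        self.dev: DevConstants = plot.genotypes[0].dev

        n = plot.n_plants
        self.n_ranks = self.dev.max_tiller_ranks
        self.max_axes = self.n_ranks + 1
        m = n * self.max_axes

        g_idx = np.array([p.genotype_id for p in plot.plants])
        gt = plot.genotypes
        self._plant_gidx = g_idx
        self.positions = np.array([p.position for p in plot.plants])
        # per-axis flattened arrays: axis (i, r) at index i*max_axes + r
        self.plant_of_axis = np.repeat(np.arange(n), self.max_axes)
        self.rank_of_axis = np.tile(np.arange(self.max_axes), n)
        ga = g_idx[self.plant_of_axis]
        self.ax_h_ms = np.array([gt[g].h_ms for g in ga])
        self.ax_lmax_b = np.array([gt[g].lmax_b for g in ga])
        self.ax_k = np.array([gt[g].extinction for g in ga])
        self.ax_par_t = np.array([gt[g].par_t for g in ga])
        self.plant_gai_c = np.array([gt[g].gai_c for g in g_idx])

        self.exists = np.zeros(m, dtype=bool)
        self.status = np.full(m, _ACTIVE, dtype=np.int8)
        self.emergence_tt = np.zeros(m)  # plant age at axis emission
        self.regress_start = np.full(m, -1, dtype=int)

        rng_delay = substream(self.seed, "emergence-delays")
        lo, hi = self.config.emergence_delay_range
        self.delays = rng_delay.uniform(lo, hi, size=n)
        for p, d in zip(plot.plants, self.delays):
            p.emergence_delay_tt = float(d)
        rng_tiller = substream(self.seed, "tiller-draws")
        self.tiller_draws = rng_tiller.uniform(size=(n, self.n_ranks))
        self.rank_emitted = np.zeros((n, self.n_ranks), dtype=bool)
        self.ceased = np.zeros(n, dtype=bool)

        self.sky: SkyDiscretization = diffuse_sky(self.config.n_sky_directions)
        max_h = max(g.h_ms for g in gt)
        self.n_layers = int(np.ceil(max_h / plot.layer_dz)) + 1

        r = self.config.gai_radius
        half_diag = 0.5 * float(np.hypot(*plot.domain))
        if r > half_diag:
            raise ValueError("gai_radius exceeds half the domain diagonal")
        dist = periodic_distances(self.positions, plot.domain)
        self.neighbor = dist <= r
        self.disc_area = np.pi * r**2

        # per-day histories
        self.tt = thermal_time(climate, self.config.t_base)
        self.dd = np.maximum(0.0, climate.temp_mean - self.config.t_base)
        self.par_hist: list[np.ndarray] = []  # (m,) mol d-1 per axis
        self.frac_hist: list[float] = []
        self.axcount_hist: list[np.ndarray] = []
        win = self.config.regression_window
        self._ratio_ring = np.full((win, m), np.nan)
        self.flowering_day = np.full(n, -1, dtype=int)
        self.day = -1
        self.maturity_day = -1
        self._last_tt = -np.inf

    # -- daily update ------------------------------------------------------

    def step_day(self) -> None:
        """Advance the stand by one day (chronological order enforced)."""
        d = self.day + 1
        if d >= len(self.climate):
            raise ValueError("climate series exhausted")
        tt_d = self.tt[d]
        if tt_d < self._last_tt:
            raise ValueError("thermal time must be non-decreasing")
        self._last_tt = tt_d
        self.day = d
        cfg, dev = self.config, self.dev

        plant_age = tt_d - self.delays  # deg Cd; < 0 before emergence
        emerged_plants = plant_age >= 0.0
        # the main stem appears the day its plant emerges
        ms = self.rank_of_axis == 0
        self.exists[ms & emerged_plants[self.plant_of_axis]] = True

        # (a) morphology
        live = self.exists & (self.status != _REGRESSED)
        ax_age = plant_age[self.plant_of_axis] - self.emergence_tt
        areas = np.zeros((len(self.exists), self.n_layers))
        if np.any(live):
            a, _ = axis_profiles(
                self.ax_h_ms[live],
                self.ax_lmax_b[live],
                self.rank_of_axis[live],
                ax_age[live],
                plant_age[self.plant_of_axis][live],
                dev,
                self.n_layers,
                self.plot.layer_dz,
            )
            areas[live] = a
        # regressing tillers lose green area linearly over the decay window
        reg = self.status == _REGRESSING
        if np.any(reg):
            decay = 1.0 - (d - self.regress_start[reg]) / cfg.regression_decay_days
            decay = np.clip(decay, 0.0, 1.0)
            areas[reg] *= decay[:, None]
            done = np.where(reg)[0][decay <= 0.0]
            self.status[done] = _REGRESSED
        self._areas = areas

        # (b) light
        incident = float(self.climate.par_incident[d])
        intercepted, transmitted = partition_light(
            areas, self.ax_k, self.sky, incident, self.plot.ground_area
        )
        self.par_hist.append(intercepted)
        flux = incident * self.plot.ground_area
        self.frac_hist.append(float(intercepted.sum() / flux) if flux > 0 else 0.0)

        # (c) cessation + emission
        axis_area = areas.sum(axis=1)  # cm2 per axis
        plant_area = np.bincount(
            self.plant_of_axis, weights=axis_area, minlength=self.plot.n_plants
        )
        if cfg.whole_plot_gai:
            gai = np.full(
                self.plot.n_plants,
                plant_area.sum() * 1e-4 / self.plot.ground_area,
            )
        else:
            gai = (self.neighbor @ plant_area) * 1e-4 / self.disc_area
        self.ceased |= emerged_plants & (gai >= self.plant_gai_c)

        ms_leaves = np.where(
            emerged_plants,
            np.minimum(dev.n_leaves, 1 + np.floor(plant_age / dev.phyllochron)),
            0,
        )
        for r in range(1, self.n_ranks + 1):
            may = (
                emerged_plants
                & ~self.ceased
                & ~self.rank_emitted[:, r - 1]
                & (ms_leaves >= r + 3)
            )
            if not np.any(may):
                continue
            # one draw per rank per plant, consumed the first eligible day
            emit = may & (self.tiller_draws[:, r - 1] < dev.emergence_probs[r - 1])
            self.rank_emitted[:, r - 1] |= may
            idx = np.where(emit)[0] * self.max_axes + r
            self.exists[idx] = True
            self.status[idx] = _ACTIVE
            self.emergence_tt[idx] = plant_age[emit]

        # (d) regression (tillers only, after the protection phase)
        self._ratio_ring[d % cfg.regression_window] = np.nan
        evaluable = (
            self.exists
            & (self.status == _ACTIVE)
            & (self.rank_of_axis >= 1)
            & (plant_age[self.plant_of_axis] >= dev.elong_start_tt)
            & (axis_area > 0)
        )
        if self.dd[d] > 0 and np.any(evaluable):
            ratio = np.full(len(self.exists), np.nan)
            # intercepted PAR per m2 of axis green area per degree-day
            ratio[evaluable] = intercepted[evaluable] / (
                axis_area[evaluable] * 1e-4 * self.dd[d]
            )
            self._ratio_ring[d % cfg.regression_window] = ratio
        valid = ~np.isnan(self._ratio_ring)
        counts = valid.sum(axis=0)
        sums = np.where(valid, self._ratio_ring, 0.0).sum(axis=0)
        means = sums / np.maximum(counts, 1)
        full = counts >= cfg.regression_window
        trigger = (
            full
            & (self.status == _ACTIVE)
            & (self.rank_of_axis >= 1)
            & self.exists
            & (means < self.ax_par_t)
        )
        self.status[trigger] = _REGRESSING
        self.regress_start[trigger] = d
        self._ratio_ring[:, trigger] = np.nan

        # bookkeeping: flowering dates and dynamics
        newly_flowering = (
            (self.flowering_day < 0) & (plant_age >= dev.flowering_tt) & emerged_plants
        )
        self.flowering_day[newly_flowering] = d
        live_now = self.exists & (self.status != _REGRESSED)
        self.axcount_hist.append(
            np.bincount(
                self.plant_of_axis[live_now], minlength=self.plot.n_plants
            ).astype(int)
        )
        if self.maturity_day < 0 and np.all(plant_age >= dev.maturity_tt):
            self.maturity_day = d

    # -- outputs -----------------------------------------------------------

    def run(self) -> StandOutputs:
        required = self.dev.maturity_tt + max(self.delays)
        if self.tt[-1] < required:
            raise ValueError(
                f"climate too short: cumulative thermal time {self.tt[-1]:.0f} "
                f"deg Cd < {required:.0f} deg Cd needed to reach maturity"
            )
        while self.maturity_day < 0:
            self.step_day()
        return self._outputs()

    def _outputs(self) -> StandOutputs:
        cfg, dev = self.config, self.dev
        surviving = self.exists & (self.status == _ACTIVE)
        per_plant = np.bincount(
            self.plant_of_axis[surviving], minlength=self.plot.n_plants
        )
        n_ears = float(np.mean(per_plant))

        par = np.vstack(self.par_hist)  # (n_days, m)
        f_tot = 0.0
        temps = self.climate.temp_mean
        for i in np.where(surviving)[0]:
            fd = self.flowering_day[self.plant_of_axis[i]]
            lo = fd - 45
            window_par = par[lo:fd, i]
            window_temp = temps[lo:fd]
            t_m45 = float(np.mean(window_temp))
            if t_m45 <= 0:
                continue
            f_tot += float(np.mean(window_par)) / t_m45

        frac = np.array(self.frac_hist)
        start = min(cfg.l_perc_start_day, len(frac) - 1)
        l_perc = float(np.mean(frac[start : self.maturity_day + 1]))
        return StandOutputs(
            n_ears=n_ears,
            l_perc=l_perc,
            f_tot=f_tot,
            tillering_dynamics=np.vstack(self.axcount_hist),
            interception_dynamics=frac,
            maturity_day=self.maturity_day,
        )

    def sync_plot(self) -> None:
        """Materialize current per-axis state back into the Plot objects."""
        names = {_ACTIVE: "active", _REGRESSING: "regressing", _REGRESSED: "regressed"}
        for pi, plant in enumerate(self.plot.plants):
            plant.axes = []
            for r in range(self.max_axes):
                i = pi * self.max_axes + r
                if not self.exists[i]:
                    continue
                status = names[int(self.status[i])] if r > 0 else "active"
                ax = Axis(
                    rank=r,
                    emergence_tt=float(self.emergence_tt[i]),
                    status=status,
                    green_area_by_layer=self._areas[i].copy(),
                )
                plant.axes.append(ax)


def simulate_stand(
    plot: Plot,
    climate: ClimateSeries,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> StandOutputs:
    """Run one stand from sowing to maturity and return its outputs."""
    return StandSimulator(plot, climate, config, seed).run()
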