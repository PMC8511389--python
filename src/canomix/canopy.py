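"""Plant development, morphology and the axis fitness proxy.

The stand simulator is individual-based: each plant carries a main stem
(rank 0) and up to ``max_tiller_ranks`` primary tillers, all developing on a
thermal-time clock.  Morphology is deliberately coarse — what matters for the
competition experiments is that the five architectural parameters (final
main-stem height H_MS, blade insertion angle phi_B, longest-blade length
LmaxB, tillering-cessation threshold GAI_c and tiller-survival threshold
PAR_t) shift green-area amount, vertical placement and light extinction in
the right directions:

* blade area grows with LmaxB (quadratically, since blade width scales with
  final blade length);
* leaves are inserted along the stem, so taller genotypes hold their area
  higher;
* sheath/internode lateral (cylinder) area contributes to interception, to
  the green area index, and to the per-area denominator of the regression
  rule — taller axes carry more non-blade area and are more prone to regress.

Heights and organ dimensions are in cm, areas in cm2; ground areas are m2
with explicit conversion at the interfaces that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import ClimateSeries

__all__ = [
    "DevConstants",
    "Genotype",
    "Axis",
    "thermal_time",
    "plant_morphology",
    "axis_profiles",
    "axis_fitness",
]


@dataclass(frozen=True)
class DevConstants:
    """Fixed developmental constants shared by all genotypes.

    Thermal times are degree-days (base 0 deg C) since plant emergence.
    """

    phyllochron: float = 110.0  # deg Cd between successive leaf emergences
    n_leaves: int = 11  # final main-stem leaf number
    flowering_tt: float = 1650.0  # deg Cd at flowering
    maturity_tt: float = 2350.0  # deg Cd at maturity
    elong_start_tt: float = 900.0  # deg Cd, start of stem elongation
    elong_end_tt: float = 1500.0  # deg Cd, stem reaches final height
    blade_width_ratio: float = 0.08  # blade width / final blade length
    blade_shape_factor: float = 0.74  # area = shape * length * width
    blade_len_base: float = 0.25  # leaf-n final length profile intercept
    blade_len_slope: float = 0.75  # leaf-n final length profile slope
    stem_diameter: float = 0.4  # cm, sheath/internode cylinder diameter
    leaf_lifespan_phyllochrons: float = 5.0  # green duration of lower leaves
    n_persistent_leaves: int = 3  # topmost leaves senesce only after flowering
    tiller_height_deficit: float = 0.05  # final-height loss per tiller rank
    max_tiller_ranks: int = 6
    emergence_probs: tuple[float, ...] = (0.95, 0.85, 0.70, 0.50, 0.30, 0.10)

    def __post_init__(self) -> None:
        for name in (
            "phyllochron",
            "n_leaves",
            "flowering_tt",
            "maturity_tt",
            "blade_width_ratio",
            "blade_shape_factor",
            "blade_len_base",
            "blade_len_slope",
            "stem_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"developmental constant {name} must be > 0")
        if not (0 < self.elong_start_tt < self.elong_end_tt):
            raise ValueError("need 0 < elong_start_tt < elong_end_tt")
        if len(self.emergence_probs) < self.max_tiller_ranks:
            raise ValueError("need one emergence probability per tiller rank")
        if any(not (0.0 <= p <= 1.0) for p in self.emergence_probs):
            raise ValueError("emergence probabilities must be in [0, 1]")


@dataclass(frozen=True)
class Genotype:
    """Architectural parameter set of one cultivar.

    h_ms    final main-stem height, cm
    phi_b   blade insertion angle from the (vertical) stem, degrees
    lmax_b  final length of the longest main-stem blade, cm
    gai_c   surrounding green-area-index threshold stopping tiller emission
    par_t   intercepted-PAR-per-area threshold for tiller survival,
            mol m-2 degCd-1 of axis green area
    """

    h_ms: float
    phi_b: float
    lmax_b: float
    gai_c: float
    par_t: float
    dev: DevConstants = field(default_factory=DevConstants)

    def __post_init__(self) -> None:
        for name in ("h_ms", "phi_b", "lmax_b", "gai_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"genotype parameter {name} must be > 0")
        if self.par_t < 0:
            raise ValueError("par_t must be >= 0")

    @property
    def extinction(self) -> float:
        """Light extinction coefficient k = sin(phi_b).

        Blade projection onto the horizontal grows with the insertion angle
        from the vertical stem: planophile leaves (large phi_b) intercept
        more per unit area than erectophile ones.
        """
        return float(np.sin(np.radians(self.phi_b)))


_STATUSES = ("active", "regressing", "regressed")


@dataclass
class Axis:
    """One axis (main stem or primary tiller) of a plant."""

    rank: int  # 0 = main stem, >= 1 = primary tiller
    emergence_tt: float  # plant thermal time at axis emergence, deg Cd
    status: str = "active"
    green_area_by_layer: np.ndarray | None = None  # cm2 per height layer
    par_daily: list = field(default_factory=list)  # mol d-1 intercepted
    fitness: float | None = None  # F_axis, mol degCd-1, set after flowering

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown axis status {self.status!r}")
        if self.rank == 0 and self.status != "active":
            raise ValueError("the main stem never regresses")


def thermal_time(series: ClimateSeries, t_base: float = 0.0) -> np.ndarray:
    """Cumulative thermal time (deg Cd) at the end of each day.

    Day d holds sum_{i<=d} max(0, temp_i - t_base); non-decreasing.
    """
    if len(series) == 0:
        raise ValueError("climate series is empty")
    return np.cumsum(np.maximum(0.0, series.temp_mean - t_base))


def axis_profiles(
    genotypes_h_ms: np.ndarray,
    genotypes_lmax_b: np.ndarray,
    ranks: np.ndarray,
    axis_age: np.ndarray,
    plant_age: np.ndarray,
    dev: DevConstants,
    n_layers: int,
    layer_dz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised green-area profiles for a batch of axes.

    Parameters are per-axis arrays; returns ``(areas, heights)`` where
    ``areas`` is (n_axes, n_layers) in cm2 (half-open layers [z, z+dz)) and
    ``heights`` is the current stem height in cm.  Axes with negative age
    (not yet emerged) have zero area and height.

    Tiller rank r carries the main-stem blade profile with the final leaf
    number reduced by r and its leaves clocked on its own age, so foliage
    runs delayed relative to the main stem; stem elongation, in contrast,
    runs on the plant clock (tillers catch up in height, with a small
    per-rank final-height deficit).  Lower leaves senesce progressively
    after a fixed lifespan; the topmost leaves persist until the global
    post-flowering senescence, which takes all green area linearly to zero
    at maturity.
    """
    n_axes = len(ranks)
    areas = np.zeros((n_axes, n_layers))
    if n_axes == 0:
        return areas, np.zeros(0)

    emerged = axis_age >= 0.0
    age = np.where(emerged, axis_age, 0.0)

    # stem height: plant-clock linear ramp between elongation start and end,
    # scaled by the rank-dependent final height
    frac = (plant_age - dev.elong_start_tt) / (dev.elong_end_tt - dev.elong_start_tt)
    h_final = genotypes_h_ms * np.maximum(
        1.0 - dev.tiller_height_deficit * ranks, 0.5
    )
    heights = h_final * np.clip(frac, 0.0, 1.0) * emerged

    # global senescence: linear green-fraction decay, flowering -> maturity
    sen = np.clip(
        (dev.maturity_tt - plant_age) / (dev.maturity_tt - dev.flowering_tt),
        0.0,
        1.0,
    )
    sen = np.where(plant_age <= dev.flowering_tt, 1.0, sen)

    n_final = np.maximum(1, dev.n_leaves - ranks)  # final leaf number per axis
    lifespan = dev.leaf_lifespan_phyllochrons * dev.phyllochron

    max_n = int(np.max(n_final))
    for leaf in range(1, max_n + 1):
        exists = (leaf <= n_final) & emerged
        if not np.any(exists):
            continue
        final_len = genotypes_lmax_b * (
            dev.blade_len_base + dev.blade_len_slope * leaf / n_final
        )
        leaf_age = age - (leaf - 1) * dev.phyllochron
        growth = np.clip(leaf_age / dev.phyllochron, 0.0, 1.0)
        # lower leaves fade out over one phyllochron at the end of their
        # lifespan; the topmost n_persistent_leaves only senesce globally
        persistent = leaf > (n_final - dev.n_persistent_leaves)
        fade = np.clip((lifespan + dev.phyllochron - leaf_age) / dev.phyllochron, 0.0, 1.0)
        green = np.where(persistent, 1.0, fade) * sen
        width = dev.blade_width_ratio * final_len
        area = dev.blade_shape_factor * (growth * final_len) * width * green
        area = np.where(exists, area, 0.0)
        # ligule insertion at fraction leaf/N of the current stem height
        z = heights * leaf / n_final
        layer = np.clip((z / layer_dz).astype(int), 0, n_layers - 1)
        np.add.at(areas, (np.arange(n_axes), layer), area)

    # sheath/internode lateral area: cylinder pi*d*h spread along the stem
    edges = np.arange(n_layers) * layer_dz
    overlap = np.clip(heights[:, None] - edges[None, :], 0.0, layer_dz)
    areas += np.pi * dev.stem_diameter * overlap * (sen * emerged)[:, None]

    return areas, heights


def plant_morphology(
    genotype: Genotype,
    axis: Axis,
    tt: float,
    n_layers: int = 80,
    layer_dz: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Green-area profile (cm2 per layer) and height (cm) of one axis at ``tt``.

    ``tt`` is plant thermal time since plant emergence; must be at or after
    the axis' own emergence.
    """
    if tt < 0:
        raise ValueError("thermal time must be >= 0")
    if tt < axis.emergence_tt:
        raise ValueError("tt precedes the axis' emergence")
    dev = genotype.dev
    areas, heights = axis_profiles(
        np.array([genotype.h_ms]),
        np.array([genotype.lmax_b]),
        np.array([axis.rank]),
        np.array([tt - axis.emergence_tt]),
        np.array([tt]),
        dev,
        n_layers,
        layer_dz,
    )
    return areas[0], float(heights[0])


def axis_fitness(par_daily: np.ndarray, temp_daily: np.ndarray) -> float:
    """Axis fitness F_axis = PAR_i45 / T_m45 (mol degCd-1).

    PAR_i45 is the mean daily PAR intercepted by the axis over the 45 days
    preceding flowering (mol d-1) and T_m45 the mean temperature over the
    same window (deg C).  This is a photothermal-quotient proxy for the
    number of grains set by the axis.
    """
    par_daily = np.asarray(par_daily, dtype=float)
    temp_daily = np.asarray(temp_daily, dtype=float)
    if par_daily.shape != (45,) or temp_daily.shape != (45,):
        raise ValueError("both windows must have exactly 45 daily entries")
    t_m45 = float(np.mean(temp_daily))
    if t_m45 <= 0:
        raise ValueError("mean temperature over the window must be > 0")
    return float(np.mean(par_daily)) / t_m45
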