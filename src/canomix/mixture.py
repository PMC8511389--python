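"""Balanced binary cultivar mixtures and overyielding.

A binary mixture is parameterized by the stand mean of each architectural
trait (ref) and the between-variety difference (diff): variety 1 receives
ref + diff/2 and variety 2 ref - diff/2.  Overyielding compares a mixture
against the mean of its two components grown in pure stands under the same
climate and the same master random seed, so that a mixture of two identical
genotypes has an overyielding of exactly 1 for every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import substream
from .canopy import DevConstants, Genotype
from .climate import ClimateSeries
from .stand import Plant, Plot, SimulationConfig, StandOutputs, simulate_stand

__all__ = [
    "PARAM_NAMES",
    "REF_RANGES",
    "DIFF_RANGES",
    "PLANT_BOUNDS",
    "MixtureSpec",
    "OYResult",
    "split_refdiff",
    "build_plot",
    "build_pure_plot",
    "run_with_pures",
    "overyielding",
]

PARAM_NAMES = ("h_ms", "phi_b", "lmax_b", "gai_c", "par_t")

# explored ranges of the stand mean (ref), the between-variety difference
# (diff), and the admissible plant-scale values of each parameter
REF_RANGES = {
    "h_ms": (65.0, 135.0),
    "phi_b": (30.0, 50.0),
    "lmax_b": (16.0, 27.0),
    "gai_c": (0.4, 0.7),
    "par_t": (0.3, 0.5),
}
DIFF_RANGES = {
    "h_ms": (-50.0, 50.0),
    "phi_b": (-40.0, 40.0),
    "lmax_b": (-16.0, 16.0),
    "gai_c": (-0.6, 0.6),
    "par_t": (-0.2, 0.2),
}
PLANT_BOUNDS = {
    "h_ms": (40.0, 160.0),
    "phi_b": (10.0, 70.0),
    "lmax_b": (8.0, 35.0),
    "gai_c": (0.1, 1.0),
    "par_t": (0.2, 0.6),
}


@dataclass(frozen=True)
class MixtureSpec:
    """ref/diff parameterization of a balanced binary mixture."""

    ref: dict[str, float]
    diff: dict[str, float]
    dev: DevConstants = field(default_factory=DevConstants)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.ref or name not in self.diff:
                raise ValueError(f"missing parameter {name!r} in the mixture spec")

    @classmethod
    def from_vector(cls, x, dev: DevConstants | None = None) -> "MixtureSpec":
        """Build from a 10-vector ordered (ref of each param, diff of each)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (10,):
            raise ValueError("expected a 10-vector (5 refs then 5 diffs)")
        ref = dict(zip(PARAM_NAMES, x[:5]))
        diff = dict(zip(PARAM_NAMES, x[5:]))
        return cls(ref=ref, diff=diff, dev=dev or DevConstants())


@dataclass(frozen=True)
class OYResult:
    """Overyielding of one output: mixture vs mean of its pure components."""

    out_mix: float
    out_pure1: float
    out_pure2: float
    oy: float


def split_refdiff(spec: MixtureSpec) -> tuple[Genotype, Genotype]:
    """Resolve a ref/diff spec into the two component genotypes.

    Variety 1 gets ref + diff/2, variety 2 gets ref - diff/2 for every
    parameter.  Values falling outside the admissible plant-scale bounds
    raise an error.
    """
    vals1, vals2 = {}, {}
    for name in PARAM_NAMES:
        v1 = spec.ref[name] + spec.diff[name] / 2.0
        v2 = spec.ref[name] - spec.diff[name] / 2.0
        lo, hi = PLANT_BOUNDS[name]
        for v, label in ((v1, "variety 1"), (v2, "variety 2")):
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(
                    f"{name}={v:.4g} for {label} outside plant-scale "
                    f"bounds [{lo}, {hi}]"
                )
        vals1[name] = min(max(v1, lo), hi)
        vals2[name] = min(max(v2, lo), hi)
    return (
        Genotype(**vals1, dev=spec.dev),
        Genotype(**vals2, dev=spec.dev),
    )


def _grid_shape(n: int) -> tuple[int, int]:
    """Near-square factorization of n (best-ratio rectangle fallback)."""
    best = (1, n)
    for r in range(1, int(np.sqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def build_plot(
    g1: Genotype,
    g2: Genotype,
    n_plants: int = 110,
    density: float = 200.0,
    seed: int = 0,
    layer_dz: float = 2.0,
) -> Plot:
    """Grid plot of a balanced binary mixture with random cultivar placement.

    Plants sit on an equidistant grid at spacing 1/sqrt(density); exactly
    ceil(n/2) plants carry genotype 1 and floor(n/2) genotype 2, their
    positions permuted by the seeded placement RNG.  The domain area equals
    n_plants / density, making the periodic cell consistent with the sowing
    density.
    """
    if n_plants < 2:
        raise ValueError("n_plants must be >= 2")
    if density <= 0:
        raise ValueError("density must be > 0")
    rows, cols = _grid_shape(n_plants)
    spacing = 1.0 / np.sqrt(density)
    domain = (cols * spacing, rows * spacing)
    labels = np.array([0] * ((n_plants + 1) // 2) + [1] * (n_plants // 2))
    rng = substream(seed, "placement")
    rng.shuffle(labels)
    plants = []
    i = 0
    for r in range(rows):
        for c in range(cols):
            pos = ((c + 0.5) * spacing, (r + 0.5) * spacing)
            plants.append(Plant(position=pos, genotype_id=int(labels[i])))
            i += 1
    return Plot(
        plants=plants,
        genotypes=[g1, g2],
        density=density,
        domain=domain,
        layer_dz=layer_dz,
        rng_seed=seed,
    )


def build_pure_plot(
    g: Genotype,
    n_plants: int = 110,
    density: float = 200.0,
    seed: int = 0,
    layer_dz: float = 2.0,
) -> Plot:
    """Pure stand of one genotype on the same grid layout as a mixture."""
    return build_plot(g, g, n_plants, density, seed, layer_dz)


def run_with_pures(
    spec: MixtureSpec,
    climate: ClimateSeries,
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_plants: int = 110,
    density: float = 200.0,
) -> tuple[StandOutputs, StandOutputs, StandOutputs]:
    """Simulate the 50/50 mixture and both pure stands, seed-matched.

    All three runs share the plot geometry, the climate and the master seed,
    so differences in outputs are attributable to the genotypes alone.
    """
    g1, g2 = split_refdiff(spec)
    mix = simulate_stand(
        build_plot(g1, g2, n_plants, density, seed), climate, config, seed
    )
    pure1 = simulate_stand(
        build_pure_plot(g1, n_plants, density, seed), climate, config, seed
    )
    pure2 = simulate_stand(
        build_pure_plot(g2, n_plants, density, seed), climate, config, seed
    )
    return mix, pure1, pure2


def overyielding(out_mix: float, out_pure1: float, out_pure2: float) -> OYResult:
    """OY = out_mix / mean(out_pure1, out_pure2)."""
    denom = 0.5 * (out_pure1 + out_pure2)
    if denom <= 0:
        raise ValueError("mean pure-stand output must be > 0 for overyielding")
    return OYResult(
        out_mix=out_mix, out_pure1=out_pure1, out_pure2=out_pure2, oy=out_mix / denom
    )
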