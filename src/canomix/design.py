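"""Maximin latin-hypercube experimental designs.

Two designs drive the analyses: a 10-dimensional design over the ref/diff
parameterization of binary mixtures, and a 5-dimensional design over the
plant-scale parameter bounds for pure stands (no trait differential).
Maximin is approximated by drawing several seeded latin-hypercube candidates
and keeping the one with the largest minimum pairwise distance in the unit
hypercube — deterministic given the seed, and adequate at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .mixture import DIFF_RANGES, PARAM_NAMES, PLANT_BOUNDS, REF_RANGES

__all__ = ["DesignMatrix", "lhs_maximin", "make_designs", "mixture_bounds", "pure_bounds"]

_DISPLAY = {"h_ms": "H_MS", "phi_b": "phi_B", "lmax_b": "LmaxB",
            "gai_c": "GAI_c", "par_t": "PAR_t"}


@dataclass(frozen=True)
class DesignMatrix:
    """Bounded LHS design with provenance."""

    points: np.ndarray  # (n, d) in original units
    bounds: np.ndarray  # (d, 2) low/high
    dim_names: tuple[str, ...]
    seed: int
    kind: str  # "mixture" | "pure" | "generic"

    def __post_init__(self) -> None:
        n, d = self.points.shape
        if self.bounds.shape != (d, 2) or len(self.dim_names) != d:
            raise ValueError("points, bounds and dim_names disagree on dimension")
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.points < lo - 1e-9) or np.any(self.points > hi + 1e-9):
            raise ValueError("design points fall outside their bounds")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def unit(self) -> np.ndarray:
        """Points rescaled to the unit hypercube."""
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (self.points - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=list(self.dim_names))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, bounds: np.ndarray, seed: int = 0, kind: str = "generic"
    ) -> "DesignMatrix":
        return cls(
            points=df.to_numpy(dtype=float),
            bounds=np.asarray(bounds, dtype=float),
            dim_names=tuple(df.columns),
            seed=seed,
            kind=kind,
        )


def _min_distance(unit_points: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    if len(unit_points) < 2:
        return np.inf
    return float(pdist(unit_points).min())


def lhs_maximin(
    n: int,
    bounds,
    seed: int,
    n_candidates: int = 20,
    dim_names: tuple[str, ...] | None = None,
    kind: str = "generic",
) -> DesignMatrix:
    """Best-of-candidates maximin LHS over the given bounds.

    Draws ``n_candidates`` seeded latin hypercubes and keeps the one whose
    minimum pairwise Euclidean distance in the unit hypercube is largest.
    Every candidate (hence the winner) satisfies the one-point-per-bin
    stratification property in every dimension.
    """
    bounds = np.asarray(bounds, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if bounds.ndim != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("each dimension needs low < high bounds")
    d = bounds.shape[0]
    ss = np.random.SeedSequence(int(seed)).spawn(max(1, n_candidates))
    best, best_dist = None, -np.inf
    for child in ss:
        sampler = qmc.LatinHypercube(d=d, seed=np.random.Generator(np.random.PCG64(child)))
        cand = sampler.random(n)
        dist = _min_distance(cand)
        if dist > best_dist:
            best, best_dist = cand, dist
    points = qmc.scale(best, bounds[:, 0], bounds[:, 1])
    names = dim_names or tuple(f"x{i}" for i in range(d))
    return DesignMatrix(
        points=points, bounds=bounds, dim_names=tuple(names), seed=int(seed), kind=kind
    )


def mixture_bounds() -> tuple[np.ndarray, tuple[str, ...]]:
    """10-D bounds: the five ref ranges then the five diff ranges."""
    bounds = [REF_RANGES[p] for p in PARAM_NAMES] + [DIFF_RANGES[p] for p in PARAM_NAMES]
    names = tuple(f"{_DISPLAY[p]}-ref" for p in PARAM_NAMES) + tuple(
        f"{_DISPLAY[p]}-diff" for p in PARAM_NAMES
    )
    return np.array(bounds, dtype=float), names


def pure_bounds() -> tuple[np.ndarray, tuple[str, ...]]:
    """5-D plant-scale bounds (no trait differential)."""
    bounds = [PLANT_BOUNDS[p] for p in PARAM_NAMES]
    names = tuple(_DISPLAY[p] for p in PARAM_NAMES)
    return np.array(bounds, dtype=float), names


def make_designs(
    n_mixture: int = 5000,
    n_pure: int = 1000,
    seed: int = 0,
    n_candidates: int = 20,
) -> tuple[DesignMatrix, DesignMatrix]:
    """The mixture (10-D ref/diff) and pure-stand (5-D) maximin LHS designs.

    Default sizes match the reference campaign (5,000 mixture runs, 1,000
    pure runs); desk-scale work passes much smaller ``n``.
    """
    mb, mnames = mixture_bounds()
    pb, pnames = pure_bounds()
    mix = lhs_maximin(n_mixture, mb, seed, n_candidates, mnames, kind="mixture")
    pure = lhs_maximin(n_pure, pb, seed + 1, n_candidates, pnames, kind="pure")
    return mix, pure
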