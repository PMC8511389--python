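"""Variance-based (Sobol) sensitivity indices of a predictor.

First-order indices (MSI) measure the share of output variance explained by
each input alone; total-order indices (TSI) add all interactions involving
the input.  Estimation uses pick-freeze Saltelli sampling (independent A and
B matrices plus the AB_i hybrids) with the Jansen estimators, replicated
over independent sub-seeds to attach a Monte-Carlo spread to every index.
Indices are always computed on a fast (metamodel) predictor, never on the
raw stand simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .kriging import KrigingModel
from .mixture import PARAM_NAMES, split_refdiff

__all__ = ["SobolEstimate", "sobol_indices", "oy_predictor"]


@dataclass(frozen=True)
class SobolEstimate:
    """Per-dimension first/total-order Sobol indices with MC spread."""

    dim_names: tuple[str, ...]
    msi: np.ndarray  # first-order indices
    tsi: np.ndarray  # total-order indices
    msi_sd: np.ndarray  # spread over replications
    tsi_sd: np.ndarray
    n_base: int
    n_rep: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dim_name": list(self.dim_names),
                "msi": self.msi,
                "msi_sd": self.msi_sd,
                "tsi": self.tsi,
                "tsi_sd": self.tsi_sd,
            }
        )

    def clipped(self) -> "SobolEstimate":
        """Reporting helper: negative MC-noise estimates clipped at 0."""
        return SobolEstimate(
            dim_names=self.dim_names,
            msi=np.clip(self.msi, 0.0, None),
            tsi=np.clip(self.tsi, 0.0, None),
            msi_sd=self.msi_sd,
            tsi_sd=self.tsi_sd,
            n_base=self.n_base,
            n_rep=self.n_rep,
            seed=self.seed,
        )


def _jansen_once(
    predictor: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    n_base: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    a = rng.uniform(size=(n_base, d))
    b = rng.uniform(size=(n_base, d))

    def f(u: np.ndarray) -> np.ndarray:
        y = np.asarray(predictor(lo + u * (hi - lo)), dtype=float).ravel()
        if np.any(~np.isfinite(y)):
            bad = np.where(~np.isfinite(y))[0][0]
            raise ValueError(
                f"predictor returned a non-finite value at {lo + u[bad] * (hi - lo)}"
            )
        return y

    fa, fb = f(a), f(b)
    var = np.var(np.concatenate([fa, fb]))
    if var == 0:
        return np.zeros(d), np.zeros(d)
    msi = np.empty(d)
    tsi = np.empty(d)
    for i in range(d):
        ab_i = a.copy()
        ab_i[:, i] = b[:, i]
        fab = f(ab_i)
        # Jansen: MSI_i = 1 - E[(f(B) - f(AB_i))^2] / (2 V)
        #         TSI_i =     E[(f(A) - f(AB_i))^2] / (2 V)
        msi[i] = 1.0 - np.mean((fb - fab) ** 2) / (2.0 * var)
        tsi[i] = np.mean((fa - fab) ** 2) / (2.0 * var)
    return msi, tsi


def sobol_indices(
    predictor: Callable[[np.ndarray], np.ndarray],
    bounds,
    n_base: int = 4096,
    n_rep: int = 10,
    seed: int = 0,
    dim_names: tuple[str, ...] | None = None,
) -> SobolEstimate:
    """Estimate first- and total-order Sobol indices of ``predictor``.

    ``predictor`` maps an (n, d) array of points in original units to n
    scalar outputs and must be deterministic.  Inputs are independent
    uniforms over ``bounds``.  ``n_rep`` independent replications give the
    sd fields; small negative estimates are reported as-is (MC noise),
    use :meth:`SobolEstimate.clipped` for display.
    """
    bounds = np.asarray(bounds, dtype=float)
    if n_base < 64:
        raise ValueError("n_base must be >= 64")
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2 to estimate a spread")
    d = bounds.shape[0]
    children = np.random.SeedSequence(int(seed)).spawn(n_rep)
    msis = np.empty((n_rep, d))
    tsis = np.empty((n_rep, d))
    for r, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        msis[r], tsis[r] = _jansen_once(predictor, bounds, n_base, rng)
    names = dim_names or tuple(f"x{i}" for i in range(d))
    return SobolEstimate(
        dim_names=tuple(names),
        msi=msis.mean(axis=0),
        tsi=tsis.mean(axis=0),
        msi_sd=msis.std(axis=0, ddof=1),
        tsi_sd=tsis.std(axis=0, ddof=1),
        n_base=int(n_base),
        n_rep=int(n_rep),
        seed=int(seed),
    )


def oy_predictor(
    mix_model: KrigingModel, pure_model: KrigingModel
) -> Callable[[np.ndarray], np.ndarray]:
    """Composite overyielding predictor over the 10-D ref/diff hypercube.

    At x = (ref, diff): OY(x) = mix(x) / mean(pure(ref + diff/2),
    pure(ref - diff/2)), where the pure metamodel is evaluated at the two
    plant-scale genotype vectors of the mixture.  Raises if the predicted
    pure-stand denominator is not positive.
    """
    if mix_model.bounds.shape[0] != 10 or pure_model.bounds.shape[0] != 5:
        raise ValueError("expected a 10-D mixture model and a 5-D pure model")

    def predict(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ref, diff = x[:, :5], x[:, 5:]
        g1 = ref + diff / 2.0
        g2 = ref - diff / 2.0
        mix_mean, _ = mix_model.predict(x)
        p1, _ = pure_model.predict(g1)
        p2, _ = pure_model.predict(g2)
        denom = 0.5 * (p1 + p2)
        if np.any(denom <= 0):
            bad = x[np.argmax(denom <= 0)]
            raise ValueError(f"non-positive pure-stand prediction at {bad}")
        return mix_mean / denom

    return predict
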