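"""Efficient Global Optimization by Expected-Improvement enrichment.

Starting from an evaluated design, each iteration refits the Kriging
metamodel on all runs so far, draws a fresh seeded latin-hypercube pool of
candidate points, and runs the (expensive) objective at the candidate
maximizing the Expected Improvement — the closed-form trade-off between a
high predicted mean and a high predictive uncertainty.  "Best" is the best
observed output; the simulator's run-to-run noise is absorbed by the model
nugget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._seeds import row_seed
from .design import DesignMatrix, lhs_maximin
from .kriging import KrigingModel, fit_kriging

__all__ = ["EGOTrace", "expected_improvement", "ego_enrich"]


@dataclass
class EGOTrace:
    """History of one enrichment run."""

    points: list = field(default_factory=list)  # chosen points, original units
    ei_values: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    best_so_far: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # (point, error message)
    initial_design_size: int = 0
    pool_size: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.atleast_2d(np.array(self.points)) if self.points else np.empty((0, 0))
        )
        df.columns = [f"x{i}" for i in range(df.shape[1])]
        df["ei"] = self.ei_values
        df["output"] = self.outputs
        df["best_so_far"] = self.best_so_far
        return df


def expected_improvement(mean, sd, best: float) -> np.ndarray:
    """EI for maximization: (m - best) Phi(u) + sd phi(u), u = (m - best)/sd.

    For sd = 0 the deterministic limit max(0, mean - best) applies.  Always
    non-negative.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be >= 0")
    imp = mean - best
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(
        sd > 0,
        imp * norm.cdf(u) + sd * norm.pdf(u),
        np.maximum(imp, 0.0),
    )
    return np.maximum(ei, 0.0)


def ego_enrich(
    simulator: Callable[[np.ndarray], float],
    initial_design: DesignMatrix,
    initial_outputs,
    n_iter: int = 50,
    pool_size: int = 10_000,
    seed: int = 0,
    fit_options: dict | None = None,
) -> tuple[DesignMatrix, np.ndarray, EGOTrace, KrigingModel]:
    """Enrich a design with ``n_iter`` EI-selected objective evaluations.

    Per iteration: refit the Kriging model on all points so far, draw a
    fresh sub-seeded LHS pool, evaluate EI at every candidate and run the
    objective at the argmax (ties broken by first index).  A failing
    objective evaluation is recorded in the trace, the point skipped and
    the iteration not counted.

    Returns the enriched design, its outputs, the trace, and the final
    fitted model.
    """
    if initial_design.n == 0:
        raise ValueError("the initial design must be non-empty")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    y = np.asarray(initial_outputs, dtype=float).copy()
    if y.shape != (initial_design.n,):
        raise ValueError("initial outputs must match the initial design size")
    fit_options = dict(fit_options or {})
    fit_options.setdefault("seed", seed)

    points = initial_design.points.copy()
    trace = EGOTrace(
        initial_design_size=initial_design.n, pool_size=pool_size, seed=int(seed)
    )
    model: KrigingModel | None = None
    it = 0
    attempts = 0
    max_attempts = 3 * max(n_iter, 1)
    while it < n_iter and attempts < max_attempts:
        attempts += 1
        design_now = DesignMatrix(
            points=points,
            bounds=initial_design.bounds,
            dim_names=initial_design.dim_names,
            seed=initial_design.seed,
            kind=initial_design.kind,
        )
        model = fit_kriging(design_now, y, **fit_options)
        best = float(np.max(y))
        pool = lhs_maximin(
            pool_size,
            initial_design.bounds,
            seed=row_seed(seed, attempts),
            n_candidates=1,
        )
        mean, sd = model.predict(pool.points)
        ei = expected_improvement(mean, sd, best)
        chosen = int(np.argmax(ei))  # argmax takes the first maximal index
        x_new = pool.points[chosen]
        try:
            y_new = float(simulator(x_new))
        except Exception as exc:  # objective failure: record and skip
            trace.failures.append((x_new.tolist(), str(exc)))
            continue
        points = np.vstack([points, x_new])
        y = np.append(y, y_new)
        it += 1
        trace.points.append(x_new.tolist())
        trace.ei_values.append(float(ei[chosen]))
        trace.outputs.append(y_new)
        trace.best_so_far.append(float(np.max(y)))

    final_design = DesignMatrix(
        points=points,
        bounds=initial_design.bounds,
        dim_names=initial_design.dim_names,
        seed=initial_design.seed,
        kind=initial_design.kind,
    )
    if model is None:  # n_iter == 0: still fit once so a model is returned
        model = fit_kriging(final_design, y, **fit_options)
    return final_design, y, trace, model
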