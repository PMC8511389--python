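"""Gaussian-process (Kriging) emulation of stand-simulation outputs.

The simulator is stochastic and too slow for the tens of thousands of
evaluations that variance-based sensitivity analysis and sequential
optimization require, so each scalar output (N_ears, L_perc, F_tot) is
emulated by a Kriging metamodel: a Gaussian process with constant trend,
anisotropic Matern 5/2 covariance, and a nugget absorbing the
simulation-to-simulation noise.  Inputs are normalized to the unit
hypercube and outputs standardized internally; both transforms are undone
at prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .design import DesignMatrix

__all__ = ["KrigingModel", "fit_kriging", "kriging_predict", "save_model", "load_model"]


@dataclass
class KrigingModel:
    """Fitted Kriging emulator over a bounded hypercube."""

    gp: GaussianProcessRegressor
    bounds: np.ndarray  # (d, 2) original-unit bounds used for normalization
    dim_names: tuple[str, ...]
    train_x: np.ndarray  # original units
    train_y: np.ndarray
    nugget: float  # estimated noise variance on the standardized scale
    constant: bool = False  # degenerate (zero-variance) training response

    def _product(self):
        k = self.gp.kernel_
        return k.k1 if k.__class__.__name__ == "Sum" else k

    @property
    def length_scales(self) -> np.ndarray:
        if self.constant:
            return np.full(self.bounds.shape[0], np.inf)
        return np.atleast_1d(self._product().k2.length_scale)

    @property
    def process_variance(self) -> float:
        if self.constant:
            return 0.0
        return float(self._product().k1.constant_value)

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def predict(self, x, return_sd: bool = True):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.bounds.shape[0]:
            raise ValueError(
                f"expected {self.bounds.shape[0]}-dimensional points, got {x.shape[1]}"
            )
        if self.constant:
            mean = np.full(len(x), float(np.mean(self.train_y)))
            return (mean, np.zeros(len(x))) if return_sd else mean
        u = self._normalize(x)
        if return_sd:
            mean, sd = self.gp.predict(u, return_std=True)
            return mean, np.maximum(sd, 0.0)
        return self.gp.predict(u)


def fit_kriging(
    design: DesignMatrix,
    y,
    nugget: float | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    kernel: str = "matern52",
) -> KrigingModel:
    """Fit a Kriging metamodel to outputs observed on a design.

    Hyperparameters maximize the log marginal likelihood with seeded
    multi-start.  The nugget (simulator noise variance) is estimated jointly
    unless ``nugget`` fixes it (0 gives an interpolating model).  A
    zero-variance response yields a flagged constant model.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n, d = design.points.shape
    if n < d + 2:
        raise ValueError(f"need at least d + 2 = {d + 2} points, got {n}")
    if y.shape != (n,):
        raise ValueError("y length must match the design size")

    base = KrigingModel(
        gp=None,  # type: ignore[arg-type]
        bounds=design.bounds,
        dim_names=design.dim_names,
        train_x=design.points.copy(),
        train_y=y.copy(),
        nugget=0.0,
    )
    if np.ptp(y) == 0.0:
        base.constant = True
        return base

    if kernel == "matern52":
        corr = Matern(length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5)
    elif kernel == "rbf":
        from sklearn.gaussian_process.kernels import RBF

        corr = RBF(length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    k = ConstantKernel(1.0, (1e-3, 1e3)) * corr
    if nugget is None:
        k = k + WhiteKernel(1e-2, (1e-10, 1e1))
        alpha = 1e-10
    else:
        alpha = max(float(nugget), 1e-10)

    gp = GaussianProcessRegressor(
        kernel=k,
        alpha=alpha,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=int(seed) % (2**31 - 1),
    )
    gp.fit(base._normalize(design.points), y)
    # report the nugget on the original output scale (normalize_y standardizes)
    y_var = float(np.var(y))
    est = float(gp.kernel_.k2.noise_level) if nugget is None else float(nugget)
    base.gp = gp
    base.nugget = est * y_var
    return base


def kriging_predict(model: KrigingModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and standard deviation at one or more points."""
    return model.predict(x, return_sd=True)


def save_model(model: KrigingModel, path: str | Path) -> None:
    """Serialize hyperparameters + training data to JSON for exact reload."""
    payload = {
        "schema": 1,
        "bounds": model.bounds.tolist(),
        "dim_names": list(model.dim_names),
        "train_x": model.train_x.tolist(),
        "train_y": model.train_y.tolist(),
        "nugget": model.nugget,
        "constant": model.constant,
    }
    if not model.constant:
        payload["kernel"] = format(model.gp.kernel_)
        payload["kernel_theta"] = model.gp.kernel_.theta.tolist()
        payload["alpha"] = float(model.gp.alpha)
        payload["has_white"] = model.gp.kernel_.__class__.__name__ == "Sum"
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> KrigingModel:
    """Reload a serialized model; refits the linear algebra with fixed
    hyperparameters (deterministic)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != 1:
        raise ValueError("unsupported model schema version")
    design = DesignMatrix(
        points=np.array(payload["train_x"], dtype=float),
        bounds=np.array(payload["bounds"], dtype=float),
        dim_names=tuple(payload["dim_names"]),
        seed=0,
        kind="generic",
    )
    y = np.array(payload["train_y"], dtype=float)
    if payload["constant"]:
        m = KrigingModel(
            gp=None,  # type: ignore[arg-type]
            bounds=design.bounds,
            dim_names=design.dim_names,
            train_x=design.points,
            train_y=y,
            nugget=0.0,
            constant=True,
        )
        return m
    d = design.bounds.shape[0]
    k = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    )
    if payload["has_white"]:
        k = k + WhiteKernel(1e-2, (1e-10, 1e1))
    k.theta = np.array(payload["kernel_theta"], dtype=float)
    gp = GaussianProcessRegressor(
        kernel=k, alpha=payload["alpha"], normalize_y=True, optimizer=None
    )
    model = KrigingModel(
        gp=gp,
        bounds=design.bounds,
        dim_names=design.dim_names,
        train_x=design.points,
        train_y=y,
        nugget=payload["nugget"],
    )
    gp.fit(model._normalize(design.points), y)
    return model
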