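"""Least-squares SVM regression with an RBF kernel, plus LOO-CV grid search.

Model
-----
Training solves the (n+1) x (n+1) linear KKT system

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma  ] [ alpha ] = [ y ]

with K[i, j] = exp(-||x_i - x_j||^2 / sigma2); predictions are
``yhat(x) = sum_i alpha_i exp(-||x - x_i||^2 / sigma2) + b``. Note the RBF
convention ``exp(-d^2 / sigma2)`` (no factor of 2), matching the classic
LS-SVM toolbox parameterization — sigma2 values are not interchangeable
with scikit-learn's ``gamma = 1/(2 sigma^2)`` convention.

Hyperparameters (gamma, sigma2) are tuned by grid search minimizing the
leave-one-out cross-validation MSE. LOO residuals are obtained from the
closed-form identity ``e_i = alpha_i / (A^{-1})_{ii}`` (diagonal of the
inverted KKT matrix), which is algebraically identical to refitting n times
and far cheaper; ``loo_mse_naive`` keeps the explicit refit loop for
cross-checking.

Inputs are used as-is (no autoscaling) unless ``scale=True`` is requested.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LSSVMModel",
    "GridConfig",
    "rbf_kernel",
    "fit_lssvm",
    "predict",
    "loo_mse",
    "loo_mse_naive",
    "grid_search",
    "save_model",
    "load_model",
]

_KKT_RTOL = 1e-8


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian kernel matrix K[i, j] = exp(-||a_i - b_j||^2 / sigma2)."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return np.exp(-cdist(A, B, "sqeuclidean") / sigma2)


@dataclass
class LSSVMModel:
    """Trained dual solution with its hyperparameters and training spectra."""

    gamma: float
    sigma2: float
    alpha: np.ndarray
    b: float
    Xtrain: np.ndarray

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return predict(self, Xnew)


def _kkt_matrix(K: np.ndarray, gamma: float) -> np.ndarray:
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    return A


def _solve_kkt(K: np.ndarray, y: np.ndarray, gamma: float) -> tuple[np.ndarray, float]:
    A = _kkt_matrix(K, gamma)
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular LS-SVM system; a smaller gamma (larger ridge jitter 1/gamma) may help"
        ) from err
    resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    if resid > _KKT_RTOL:
        raise np.linalg.LinAlgError(
            f"ill-conditioned LS-SVM system (relative KKT residual {resid:.2e}); "
            "a smaller gamma may help"
        )
    return sol[1:], float(sol[0])


def fit_lssvm(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LSSVMModel:
    """Train an LS-SVM by solving the KKT system directly."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[0] < 2:
        raise ValueError("LS-SVM needs at least two training samples")
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    K = rbf_kernel(X, X, sigma2)
    alpha, b = _solve_kkt(K, y, gamma)
    return LSSVMModel(gamma=float(gamma), sigma2=float(sigma2), alpha=alpha, b=b, Xtrain=X.copy())


def predict(model: LSSVMModel, Xnew: np.ndarray) -> np.ndarray:
    """Dual-form prediction yhat(x) = sum_i alpha_i K(x, x_i) + b."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.size == 0:
        return np.empty(0)
    Xnew = np.atleast_2d(Xnew)
    if Xnew.shape[1] != model.Xtrain.shape[1]:
        raise ValueError(
            f"feature count {Xnew.shape[1]} does not match training count {model.Xtrain.shape[1]}"
        )
    return rbf_kernel(Xnew, model.Xtrain, model.sigma2) @ model.alpha + model.b


def loo_mse(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Leave-one-out CV mean squared error via the closed-form LOO residuals.

    For the KKT matrix A, the LOO residual of sample i is
    ``alpha_i / (A^{-1})_{ii}``; this equals the naive n-refit loop exactly
    (up to round-off).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("LOO-CV needs at least three samples")
    K = rbf_kernel(X, X, sigma2)
    A = _kkt_matrix(K, gamma)
    Ainv = np.linalg.inv(A)
    sol = Ainv @ np.concatenate([[0.0], y])
    alpha = sol[1:]
    diag = np.diag(Ainv)[1:]
    residuals = alpha / diag
    return float(np.mean(residuals**2))


def loo_mse_naive(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Reference LOO-CV: explicitly refit the model n times. O(n^4); small n only."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    errs = np.empty(y.size)
    for i in range(y.size):
        keep = np.arange(y.size) != i
        model = fit_lssvm(X[keep], y[keep], gamma, sigma2)
        errs[i] = predict(model, X[i : i + 1])[0] - y[i]
    return float(np.mean(errs**2))


@dataclass
class GridConfig:
    """Log-spaced (gamma, sigma2) grid over the stated search box [1, 5000]^2."""

    gamma_bounds: tuple = (1.0, 5000.0)
    sigma2_bounds: tuple = (1.0, 5000.0)
    resolution: int = 20

    def __post_init__(self) -> None:
        for lo, hi in (self.gamma_bounds, self.sigma2_bounds):
            if not 0 < lo < hi:
                raise ValueError("bounds must satisfy 0 < lower < upper")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")

    def gamma_grid(self) -> np.ndarray:
        return np.geomspace(*self.gamma_bounds, self.resolution)

    def sigma2_grid(self) -> np.ndarray:
        return np.geomspace(*self.sigma2_bounds, self.resolution)


def grid_search(
    X: np.ndarray, y: np.ndarray, cfg: GridConfig | None = None
) -> tuple[float, float, float]:
    """Exhaustive grid search minimizing LOO-CV MSE.

    Ties prefer the smaller gamma, then the smaller sigma2 (the grids are
    iterated in increasing order with strict improvement). Grid points whose
    system fails to solve are skipped with a warning; if every point fails,
    an error is raised. Returns ``(gamma, sigma2, loo_mse)``.
    """
    cfg = cfg or GridConfig()
    best: tuple[float, float, float] | None = None
    for g in cfg.gamma_grid():
        for s2 in cfg.sigma2_grid():
            try:
                mse = loo_mse(X, y, g, s2)
            except np.linalg.LinAlgError as err:
                warnings.warn(f"grid point (gamma={g:g}, sigma2={s2:g}) skipped: {err}", stacklevel=2)
                continue
            if best is None or mse < best[2]:
                best = (float(g), float(s2), mse)
    if best is None:
        raise RuntimeError("every grid point failed to solve")
    return best


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: LSSVMModel, path: str) -> None:
    """Self-describing JSON serialization (hyperparameters, duals, data hash)."""
    payload = {
        "format": "hyperssc-lssvm-1",
        "kernel": "rbf exp(-d^2/sigma2)",
        "gamma": model.gamma,
        "sigma2": model.sigma2,
        "b": model.b,
        "alpha": model.alpha.tolist(),
        "Xtrain": model.Xtrain.tolist(),
        "xtrain_sha256": hashlib.sha256(np.ascontiguousarray(model.Xtrain).tobytes()).hexdigest(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> LSSVMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "hyperssc-lssvm-1":
        raise ValueError("not a hyperssc LS-SVM model file")
    Xtrain = np.asarray(payload["Xtrain"], dtype=float)
    digest = hashlib.sha256(np.ascontiguousarray(Xtrain).tobytes()).hexdigest()
    if digest != payload["xtrain_sha256"]:
        raise ValueError("training-data hash mismatch; model file corrupted")
    return LSSVMModel(
        gamma=payload["gamma"],
        sigma2=payload["sigma2"],
        alpha=np.asarray(payload["alpha"], dtype=float),
        b=payload["b"],
        Xtrain=Xtrain,
    )
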