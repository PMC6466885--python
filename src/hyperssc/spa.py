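"""Successive projections algorithm (SPA) for characteristic-wavelength selection.

SPA is a forward selector designed to minimize collinearity: starting from a
seed wavelength, each step appends the wavelength whose spectral column has
the largest norm after projecting out everything already selected, so no
near-duplicate band is ever picked twice. Candidate subsets (every start
column x every size in a range) are scored by the validation RMSE of an
ordinary least-squares model restricted to the subset, and the best
(smallest-RMSE) chain wins.

Columns are mean-centered before the projections (no autoscaling). The
selection order of the winning chain is reported as descending importance.
No backward-elimination refinement is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SPAConfig", "SPAResult", "spa_chain", "evaluate_subset", "spa_select"]

_RANK_TOL = 1e-10


@dataclass
class SPAConfig:
    """Subset-size range for the SPA search."""

    n_min: int = 3
    n_max: int = 24

    def __post_init__(self) -> None:
        if not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")


@dataclass
class SPAResult:
    """Winning wavelength subset and the full RMSE-versus-size record.

    ``selected`` holds column indices in within-chain selection order
    (descending importance); ``rmse_curve`` has one row per evaluated
    (start, size) candidate.
    """

    selected: np.ndarray
    best_rmse: float
    rmse_curve: pd.DataFrame
    wavelengths_nm: np.ndarray | None = None

    def to_csv(self, selected_path: str, curve_path: str | None = None) -> None:
        sel = pd.DataFrame({"rank": np.arange(1, len(self.selected) + 1), "column": self.selected})
        if self.wavelengths_nm is not None:
            sel["wavelength_nm"] = self.wavelengths_nm
        sel.to_csv(selected_path, index=False)
        if curve_path is not None:
            self.rmse_curve.to_csv(curve_path, index=False)


def spa_chain(Xcal: np.ndarray, start: int, length: int) -> np.ndarray:
    """One SPA projection chain of ``length`` columns beginning at ``start``.

    Columns are mean-centered internally. At each step the column with the
    largest residual norm (after orthogonal projection onto the complement
    of the selected columns' span) is appended; ties break to the lowest
    column index. If every remaining residual is numerically zero the chain
    is truncated with a warning (rank deficiency).
    """
    X = np.asarray(Xcal, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start column {start} outside [0, {p})")
    if length < 1:
        raise ValueError("length must be >= 1")
    R = X - X.mean(axis=0)  # residual columns, updated in place
    ref_norm = np.linalg.norm(R, axis=0).max()
    chain = [start]
    for _ in range(length - 1):
        q = R[:, chain[-1]].copy()
        nq = np.linalg.norm(q)
        if nq <= _RANK_TOL * max(ref_norm, 1.0):
            break
        q /= nq
        R -= np.outer(q, q @ R)  # project every column off the new direction
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= _RANK_TOL * max(ref_norm, 1.0):
            warnings.warn(
                f"SPA chain from column {start} truncated at {len(chain)} of {length}: "
                "remaining columns are in the span of the selected ones",
                stacklevel=2,
            )
            break
        chain.append(nxt)
    return np.array(chain, dtype=int)


def evaluate_subset(Xcal, ycal, Xval, yval, subset) -> float:
    """Validation RMSE of an OLS model (with intercept) on the given columns.

    A rank-deficient design falls back to the minimum-norm least-squares
    solution with a warning.
    """
    subset = np.asarray(subset, dtype=int)
    Xcal = np.asarray(Xcal, dtype=float)
    if subset.size >= Xcal.shape[0]:
        raise ValueError("subset size must be smaller than the number of calibration samples")
    A = np.column_stack([np.ones(Xcal.shape[0]), Xcal[:, subset]])
    coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(ycal, dtype=float), rcond=None)
    if rank < A.shape[1]:
        warnings.warn("singular normal equations; using the minimum-norm solution", stacklevel=2)
    Av = np.column_stack([np.ones(np.asarray(Xval).shape[0]), np.asarray(Xval, float)[:, subset]])
    resid = Av @ coef - np.asarray(yval, dtype=float)
    return float(np.sqrt(np.mean(resid**2)))


def spa_select(
    Xcal,
    ycal,
    Xval,
    yval,
    cfg: SPAConfig | None = None,
    wavelengths: np.ndarray | None = None,
) -> SPAResult:
    """Full SPA search: chains from every start column, sizes in [n_min, n_max].

    Returns the candidate minimizing validation RMSE; ties prefer the
    smaller subset, then the lower start index.
    """
    cfg = cfg or SPAConfig()
    Xcal = np.asarray(Xcal, dtype=float)
    n, p = Xcal.shape
    if cfg.n_max > min(p, n - 1):
        raise ValueError(f"n_max {cfg.n_max} exceeds min(p, n_cal - 1) = {min(p, n - 1)}")

    records = []
    best = None  # (rmse, size, start, chain_prefix)
    for start in range(p):
        chain = spa_chain(Xcal, start, cfg.n_max)
        for size in range(cfg.n_min, len(chain) + 1):
            subset = chain[:size]
            r = evaluate_subset(Xcal, ycal, Xval, yval, subset)
            records.append({"start": start, "size": size, "rmse": r})
            key = (r, size, start)
            if best is None or key < (best[0], best[1], best[2]):
                best = (r, size, start, subset.copy())
    if best is None:
        raise ValueError("no candidate subset could be evaluated")
    curve = pd.DataFrame.from_records(records)
    sel = best[3]
    return SPAResult(
        selected=sel,
        best_rmse=best[0],
        rmse_curve=curve,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths, float)[sel],
    )
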