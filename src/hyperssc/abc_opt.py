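"""Artificial bee colony (ABC) search over LS-SVM hyperparameters (gamma, sigma2).

The colony follows the classic employed / onlooker / scout scheme:

1. SN food sources (candidate positions) are initialized uniformly at random
   inside the search box; SN equals half the swarm.
2. Employed phase: each source tries one neighbor move
   ``v_j = x_ij + phi * (x_ij - x_kj)`` (one random coordinate j, random
   partner k != i, phi ~ U(-1, 1), clamped to bounds) and keeps it only if
   the fitness improves (greedy); otherwise the source's trial counter grows.
3. Onlooker phase: SN onlookers cycle through the sources, probing source i
   with probability ``P_i = 0.9 * fit_i / max(fit) + 0.1`` and applying the
   same greedy neighbor move.
4. Scout phase: any source whose trial counter exceeds the limit is
   abandoned and re-randomized.
5. The global best position/objective is memorized across all evaluations,
   so the per-iteration best-MSE trace is non-increasing.
6. The whole search is repeated ``n_runs`` times with independent seeds to
   assess robustness.

Fitness maps the objective f_obj (here: prediction-set MSE of the LS-SVM)
through ``fit = 1/(1 + f_obj)`` for f_obj >= 0 and ``1 + |f_obj|``
otherwise, so lower MSE means higher fitness and higher selection
probability.

The default search box is the stated [1, 5000]^2 range for (gamma, sigma2);
``WIDE_BOUNDS`` extends gamma to 1e5 for searches that want to reach the
large-gamma near-interpolation regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lssvm import fit_lssvm, predict, rbf_kernel, _solve_kkt

__all__ = [
    "ABCConfig",
    "FoodSource",
    "ABCResult",
    "DEFAULT_BOUNDS",
    "WIDE_BOUNDS",
    "fitness",
    "objective_mse",
    "make_mse_objective",
    "selection_probability",
    "neighbor",
    "run_abc",
    "run_repeated",
]

DEFAULT_BOUNDS = ((1.0, 5000.0), (1.0, 5000.0))
#: wider gamma range for searches targeting the near-interpolation regime
WIDE_BOUNDS = ((1.0, 1e5), (1.0, 5000.0))


@dataclass
class ABCConfig:
    """Colony control parameters (defaults are the study settings)."""

    swarm_size: int = 60
    n_sources: int = 30
    limit: int = 120
    max_iter: int = 30
    dim: int = 2
    bounds: tuple = DEFAULT_BOUNDS
    n_runs: int = 10

    def __post_init__(self) -> None:
        if self.n_sources != self.swarm_size // 2:
            raise ValueError("n_sources (SN) must equal swarm_size / 2")
        if self.limit <= 0 or self.max_iter < 1 or self.n_runs < 1:
            raise ValueError("limit, max_iter and n_runs must be positive")
        if len(self.bounds) != self.dim:
            raise ValueError("one (lower, upper) pair per dimension is required")
        for lo, hi in self.bounds:
            if not np.isfinite(lo) or not np.isfinite(hi) or lo >= hi:
                raise ValueError("bounds must be finite with lower < upper")


@dataclass
class FoodSource:
    """One candidate position with its objective, fitness and trial counter."""

    position: np.ndarray
    f_obj: float
    fit: float
    trial: int = 0


@dataclass
class ABCResult:
    """Outcome of one colony run."""

    best_position: np.ndarray
    best_mse: float
    trace: np.ndarray  # global best MSE after each iteration (non-increasing)
    n_evals: int


def fitness(f_obj: float) -> float:
    """fit = 1/(1 + f_obj) if f_obj >= 0 else 1 + |f_obj|."""
    if np.isnan(f_obj):
        raise ValueError("objective value is NaN")
    return 1.0 / (1.0 + f_obj) if f_obj >= 0 else 1.0 + abs(f_obj)


def selection_probability(fits: np.ndarray) -> np.ndarray:
    """P_i = 0.9 * fit_i / max(fit) + 0.1 (values in (0.1, 1.0])."""
    fits = np.asarray(fits, dtype=float)
    if fits.size == 0:
        raise ValueError("empty fitness vector")
    m = fits.max()
    if m <= 0:
        raise ValueError("all fitness values are zero; selection probabilities undefined")
    return 0.9 * fits / m + 0.1


def neighbor(x_i: np.ndarray, x_k: np.ndarray, phi: float, j: int, bounds=DEFAULT_BOUNDS) -> np.ndarray:
    """Candidate position: coordinate j moved by phi * (x_ij - x_kj), clamped."""
    v = np.asarray(x_i, dtype=float).copy()
    v[j] = x_i[j] + phi * (x_i[j] - x_k[j])
    lo, hi = bounds[j]
    v[j] = min(max(v[j], lo), hi)
    return v


def objective_mse(params, Xcal, ycal, Xpred, ypred) -> float:
    """Prediction-set MSE of an LS-SVM trained at (gamma, sigma2) = params.

    A fit failure yields +inf (the source becomes unattractive) with a
    warning rather than aborting the search.
    """
    gamma, sigma2 = float(params[0]), float(params[1])
    if gamma <= 0 or sigma2 <= 0:
        raise ValueError("gamma and sigma2 must be positive")
    try:
        model = fit_lssvm(Xcal, ycal, gamma, sigma2)
    except np.linalg.LinAlgError as err:
        warnings.warn(f"LS-SVM fit failed at (gamma={gamma:g}, sigma2={sigma2:g}): {err}", stacklevel=2)
        return float("inf")
    resid = predict(model, Xpred) - np.asarray(ypred, dtype=float)
    return float(np.mean(resid**2))


def make_mse_objective(Xcal, ycal, Xpred, ypred):
    """Fast closure over fixed data: precomputes squared distances once.

    Returns a callable ``params -> prediction-set MSE`` equal to
    :func:`objective_mse` on the same data.
    """
    from scipy.spatial.distance import cdist

    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    ypred = np.asarray(ypred, dtype=float).ravel()
    d2_cal = cdist(Xcal, Xcal, "sqeuclidean")
    d2_cross = cdist(np.atleast_2d(np.asarray(Xpred, float)), Xcal, "sqeuclidean")

    def objective(params) -> float:
        gamma, sigma2 = float(params[0]), float(params[1])
        if gamma <= 0 or sigma2 <= 0:
            raise ValueError("gamma and sigma2 must be positive")
        try:
            alpha, b = _solve_kkt(np.exp(-d2_cal / sigma2), ycal, gamma)
        except np.linalg.LinAlgError as err:
            warnings.warn(f"LS-SVM fit failed at (gamma={gamma:g}, sigma2={sigma2:g}): {err}", stacklevel=2)
            return float("inf")
        resid = np.exp(-d2_cross / sigma2) @ alpha + b - ypred
        return float(np.mean(resid**2))

    return objective


def _cache_key(x: np.ndarray) -> tuple:
    return tuple(float(f"{v:.12g}") for v in x)


def run_abc(objective, cfg: ABCConfig | None = None, seed: int = 0, cache: dict | None = None) -> ABCResult:
    """One seeded colony run minimizing ``objective`` over cfg.bounds.

    ``cache`` (optional dict) memoizes objective values keyed on the rounded
    position; pass a shared dict to reuse evaluations across runs.
    """
    cfg = cfg or ABCConfig()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    cache = {} if cache is None else cache
    n_evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_evals
        key = _cache_key(x)
        if key not in cache:
            cache[key] = float(objective(x))
            n_evals += 1
        return cache[key]

    best_x: np.ndarray | None = None
    best_f = float("inf")

    def make_source(x: np.ndarray) -> FoodSource:
        nonlocal best_x, best_f
        f = evaluate(x)
        if f < best_f:
            best_f, best_x = f, x.copy()
        return FoodSource(position=x, f_obj=f, fit=fitness(f))

    sources = [make_source(lo + rng.random(cfg.dim) * (hi - lo)) for _ in range(cfg.n_sources)]

    def probe(i: int) -> None:
        src = sources[i]
        k = int(rng.integers(cfg.n_sources - 1))
        k = k + 1 if k >= i else k
        j = int(rng.integers(cfg.dim))
        phi = rng.uniform(-1.0, 1.0)
        cand = neighbor(src.position, sources[k].position, phi, j, cfg.bounds)
        f = evaluate(cand)
        nonlocal best_x, best_f
        if f < best_f:
            best_f, best_x = f, cand.copy()
        fit = fitness(f)
        if fit > src.fit:
            sources[i] = FoodSource(position=cand, f_obj=f, fit=fit, trial=0)
        else:
            src.trial += 1

    trace = np.empty(cfg.max_iter)
    for it in range(cfg.max_iter):
        for i in range(cfg.n_sources):  # employed phase
            probe(i)
        fits = np.array([s.fit for s in sources])
        if fits.max() > 0:  # onlooker phase
            probs = selection_probability(fits)
            t, i = 0, 0
            while t < cfg.n_sources:
                if rng.random() < probs[i]:
                    t += 1
                    probe(i)
                i = (i + 1) % cfg.n_sources
        for i, src in enumerate(sources):  # scout phase
            if src.trial > cfg.limit:
                sources[i] = make_source(lo + rng.random(cfg.dim) * (hi - lo))
        trace[it] = best_f

    if not np.isfinite(best_f):
        raise RuntimeError("ABC failed: the objective never returned a finite value")
    return ABCResult(best_position=best_x, best_mse=best_f, trace=trace, n_evals=n_evals)


def run_repeated(
    objective, cfg: ABCConfig | None = None, seed: int = 0
) -> tuple[list[ABCResult], dict]:
    """cfg.n_runs independent colony runs plus a robustness summary.

    Objective evaluations are cached across runs (the objective is
    deterministic in the position). The summary reports each run's best MSE,
    their spread, and the overall winner.
    """
    cfg = cfg or ABCConfig()
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_runs)
    cache: dict = {}
    results = [run_abc(objective, cfg, seed=int(s), cache=cache) for s in run_seeds]
    best_mses = np.array([r.best_mse for r in results])
    winner = int(np.argmin(best_mses))
    summary = {
        "best_mses": best_mses,
        "best_positions": np.array([r.best_position for r in results]),
        "winner": winner,
        "winner_mse": float(best_mses[winner]),
        "spread": float(best_mses.max() - best_mses.min()),
    }
    return results, summary
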