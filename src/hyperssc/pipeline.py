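"""End-to-end SSC modeling workflow on synthetic jujube data.

Chains the full analysis: dataset generation -> band cropping (950-1675 nm)
-> verification draw + Kennard-Stone splits -> full-spectrum grid-search
LS-SVM -> SPA wavelength selection -> grid-search and ABC-tuned LS-SVM on
the selected wavelengths -> evaluation metrics on the prediction and
verification sets.

Note: the ABC minimizes the *prediction-set* MSE (the study design), which
leaks the prediction set into model selection; pass ``abc_on_holdout=True``
to tune on the verification set instead and keep the prediction metrics
honest.
"""

from __future__ import annotations

import numpy as np

from . import metrics
from .abc_opt import ABCConfig, make_mse_objective, run_repeated
from .dataset import make_splits
from .hypercube import HyperCube, crop_bands
from .lssvm import GridConfig, fit_lssvm, grid_search, predict
from .spa import SPAConfig, spa_select
from .synthetic import SpectralModel, generate_dataset

__all__ = ["run_ssc_pipeline"]


def _model_report(Xcal, ycal, Xeval, yeval, gamma, sigma2) -> dict:
    model = fit_lssvm(Xcal, ycal, gamma, sigma2)
    cal = metrics.evaluate(ycal, predict(model, Xcal))
    pred = metrics.evaluate(yeval, predict(model, Xeval))
    return {
        "model": model,
        "gamma": gamma,
        "sigma2": sigma2,
        "r2_cal": cal.r2,
        "rmsec": cal.rmse,
        "r2_pred": pred.r2,
        "rmsep": pred.rmse,
        "rpd": pred.rpd,
        "bias": pred.bias,
        "slope": pred.slope,
    }


def run_ssc_pipeline(
    seed: int = 0,
    n_per_stage: int = 150,
    model: SpectralModel | None = None,
    crop: tuple = (950.0, 1675.0),
    spa_cfg: SPAConfig | None = None,
    grid_cfg: GridConfig | None = None,
    abc_cfg: ABCConfig | None = None,
    full_spectrum: bool = True,
    abc_on_holdout: bool = False,
) -> dict:
    """Run the whole workflow and return datasets, models and metrics.

    Returns a dict with the dataset, the split, the SPA result, and one
    report per model ("fullspec_gs", "spa_gs", "spa_abc"), each containing
    the fitted model and its calibration/prediction statistics; the
    "spa_abc" entry also carries the per-run ABC summary.
    """
    model = model or SpectralModel()
    rng = np.random.default_rng(seed)
    ds = generate_dataset(n_per_stage=n_per_stage, model=model, seed=int(rng.integers(2**31 - 1)))

    keep = (ds.wavelengths >= crop[0]) & (ds.wavelengths <= crop[1])
    X = ds.X[:, keep]
    wavelengths = ds.wavelengths[keep]

    split = make_splits(ds, seed=int(rng.integers(2**31 - 1)))
    cal, pred, ver = split.calibration, split.prediction, split.verification
    Xcal, ycal = X[cal], ds.y[cal]
    Xpred, ypred = X[pred], ds.y[pred]
    Xver, yver = X[ver], ds.y[ver]

    out: dict = {"dataset": ds, "split": split, "wavelengths": wavelengths}

    if full_spectrum:
        g, s2, _ = grid_search(Xcal, ycal, grid_cfg)
        out["fullspec_gs"] = _model_report(Xcal, ycal, Xpred, ypred, g, s2)

    spa_res = spa_select(Xcal, ycal, Xpred, ypred, spa_cfg, wavelengths=wavelengths)
    out["spa"] = spa_res
    sel = spa_res.selected
    Xcal_s, Xpred_s, Xver_s = Xcal[:, sel], Xpred[:, sel], Xver[:, sel]

    g, s2, _ = grid_search(Xcal_s, ycal, grid_cfg)
    out["spa_gs"] = _model_report(Xcal_s, ycal, Xpred_s, ypred, g, s2)
    out["spa_gs"]["verification"] = metrics.evaluate(yver, predict(out["spa_gs"]["model"], Xver_s))

    tune_X, tune_y = (Xver_s, yver) if abc_on_holdout else (Xpred_s, ypred)
    objective = make_mse_objective(Xcal_s, ycal, tune_X, tune_y)
    abc_cfg = abc_cfg or ABCConfig()
    runs, summary = run_repeated(objective, abc_cfg, seed=int(rng.integers(2**31 - 1)))
    best = summary["best_positions"][summary["winner"]]
    out["spa_abc"] = _model_report(Xcal_s, ycal, Xpred_s, ypred, float(best[0]), float(best[1]))
    out["spa_abc"]["verification"] = metrics.evaluate(yver, predict(out["spa_abc"]["model"], Xver_s))
    out["spa_abc"]["runs"] = runs
    out["spa_abc"]["summary"] = summary

    # head-to-head: each ABC run's best prediction-set MSE vs the grid model's
    grid_pred_mse = out["spa_gs"]["rmsep"] ** 2
    out["abc_vs_grid_wins"] = int(np.sum(summary["best_mses"] <= grid_pred_mse))
    return out
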