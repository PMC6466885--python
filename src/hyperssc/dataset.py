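"""Spectral datasets and the calibration / prediction / verification split workflow.

The sampling design mirrors the standard multi-maturity chemometric layout:
for every maturity stage, a fixed number of samples is first drawn at random
as an independent verification set; the remainder is split into calibration
and prediction sets by the Kennard-Stone (KS) maximin-distance algorithm.
With the default 150 samples per stage and four stages this yields pooled
sets of 360 calibration, 120 prediction and 120 verification samples
(90/30/30 per stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "Split",
    "verification_draw",
    "kennard_stone",
    "make_splits",
]

STAGES = ("immature", "white_mature", "crisp_mature", "full_mature")


@dataclass
class SpectralDataset:
    """Mean reflectance spectra with reference SSC values and stage labels.

    Attributes
    ----------
    X : ndarray, shape (n, p)
        One mean reflectance spectrum per sample.
    wavelengths : ndarray, shape (p,)
        Band centers in nm, strictly increasing.
    y : ndarray, shape (n,)
        Reference soluble-solids content in %.
    stage : ndarray of str, shape (n,)
        Maturity-stage label per sample.
    ids : ndarray of str, shape (n,)
        Sample identifiers.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    stage: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.stage = np.asarray(self.stage)
        self.ids = np.asarray(self.ids)
        n, p = self.X.shape
        if self.wavelengths.shape != (p,):
            raise ValueError("wavelength vector length must equal the number of spectral columns")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name, vec in (("y", self.y), ("stage", self.stage), ("ids", self.ids)):
            if vec.shape != (n,):
                raise ValueError(f"{name} must have one entry per sample")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("dataset contains missing or non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path: str) -> None:
        """Wide-format export: sample_id, stage, ssc_pct, then one column per wavelength."""
        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "ssc_pct", self.y)
        df.insert(0, "stage", self.stage)
        df.insert(0, "sample_id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SpectralDataset":
        df = pd.read_csv(path)
        meta = ["sample_id", "stage", "ssc_pct"]
        wl_cols = [c for c in df.columns if c not in meta]
        return cls(
            X=df[wl_cols].to_numpy(float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            y=df["ssc_pct"].to_numpy(float),
            stage=df["stage"].to_numpy(),
            ids=df["sample_id"].to_numpy(),
        )


@dataclass
class Split:
    """Disjoint calibration / prediction / verification index sets.

    ``per_stage`` maps each stage label to its own (calibration, prediction,
    verification) index triple; the pooled sets are their concatenations.
    """

    calibration: np.ndarray
    prediction: np.ndarray
    verification: np.ndarray
    per_stage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pools = [np.asarray(s) for s in (self.calibration, self.prediction, self.verification)]
        allidx = np.concatenate(pools)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split index sets overlap")

    def membership_frame(self, ids: np.ndarray) -> pd.DataFrame:
        """Long-format membership table (sample_id, set) for CSV export."""
        rows = []
        for name, idx in (
            ("calibration", self.calibration),
            ("prediction", self.prediction),
            ("verification", self.verification),
        ):
            rows.extend({"sample_id": ids[i], "set": name} for i in idx)
        return pd.DataFrame(rows)


def verification_draw(
    ds: SpectralDataset, n_per_stage: int = 30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly reserve ``n_per_stage`` samples per stage as a verification set.

    Uniform draw without replacement within each stage, reproducible by seed.
    Returns ``(remaining, verification)`` index arrays (sorted).
    """
    rng = np.random.default_rng(seed)
    verification: list[np.ndarray] = []
    for stage in np.unique(ds.stage):
        stage_idx = np.flatnonzero(ds.stage == stage)
        if stage_idx.size <= n_per_stage:
            raise ValueError(
                f"stage {stage!r} has {stage_idx.size} samples, cannot reserve {n_per_stage}"
            )
        if n_per_stage > 0:
            verification.append(rng.choice(stage_idx, size=n_per_stage, replace=False))
    ver = np.sort(np.concatenate(verification)) if verification else np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(len(ds)), ver)
    return remaining, ver


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Kennard-Stone maximin selection of ``n_select`` rows of ``X``.

    The first two picks are the pair at maximal Euclidean distance; every
    subsequent pick maximizes its minimum distance to the already-selected
    rows. Ties break to the lowest row index, making the output
    deterministic. Returns the selected row indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")

    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    if d2.max() <= 0.0:
        raise ValueError("all rows are identical; Kennard-Stone is undefined")

    # initial pair: lexicographically smallest among maximal-distance pairs
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    first = (min(i, j), max(i, j))
    selected = [int(first[0]), int(first[1])]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d2))  # argmax returns the lowest index on ties
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[nxt])
        min_d2[nxt] = -np.inf
    return np.array(selected, dtype=int)


def make_splits(
    ds: SpectralDataset,
    n_verification: int = 30,
    n_calibration: int = 90,
    seed: int = 0,
) -> Split:
    """The full splitting workflow, applied independently within each stage.

    Per stage: ``n_verification`` samples are drawn at random; Kennard-Stone
    on the remaining spectra selects the ``n_calibration`` calibration
    samples (the KS-ranked prefix); the rest form the prediction set. Pooled
    sets are concatenations over stages. Defaults reproduce the 90/30/30
    per-stage (360/120/120 pooled) design for 150 samples per stage.
    """
    remaining, ver = verification_draw(ds, n_verification, seed)
    cal_parts: list[np.ndarray] = []
    pred_parts: list[np.ndarray] = []
    per_stage: dict = {}
    for stage in np.unique(ds.stage):
        stage_rem = remaining[ds.stage[remaining] == stage]
        if n_calibration >= stage_rem.size:
            raise ValueError(
                f"stage {stage!r}: {stage_rem.size} samples left after the verification "
                f"draw, cannot select {n_calibration} for calibration and keep a prediction set"
            )
        order = kennard_stone(ds.X[stage_rem], n_calibration)
        cal = np.sort(stage_rem[order])
        pred = np.setdiff1d(stage_rem, cal)
        stage_ver = ver[ds.stage[ver] == stage]
        per_stage[str(stage)] = (cal, pred, stage_ver)
        cal_parts.append(cal)
        pred_parts.append(pred)
    return Split(
        calibration=np.sort(np.concatenate(cal_parts)),
        prediction=np.sort(np.concatenate(pred_parts)),
        verification=ver,
        per_stage=per_stage,
    )
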