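"""Per-pixel SSC prediction maps: fruit segmentation, pixel-wise regression, rendering.

Every masked pixel's spectrum is sampled at the model's wavelengths (nearest
band within a tolerance) and pushed through the trained LS-SVM; the
predictions are rearranged on the image grid into a 2-D SSC map displayed on
a fixed 0-60 % blue-to-red scale, so maps from different fruits and stages
are directly comparable. The background is masked out first and never
predicted. Display clips values outside [0, 60] to the scale ends; the
numeric array keeps the raw predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage

from .hypercube import HyperCube
from .lssvm import LSSVMModel, predict

__all__ = ["SSCMap", "segment_fruit", "predict_pixels", "render_map"]

#: display scale in % SSC (fixed so all maps are comparable)
SCALE = (0.0, 60.0)


@dataclass
class SSCMap:
    """Per-pixel predicted SSC (%) with its fruit mask and fixed display scale."""

    values: np.ndarray  # 2-D float; NaN outside the mask
    mask: np.ndarray  # 2-D bool
    scale: tuple = SCALE

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        if np.any(np.isfinite(self.values[~self.mask])):
            raise ValueError("background pixels must carry no SSC value")

    def masked_mean(self) -> float:
        return float(np.nanmean(self.values[self.mask]))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)


def segment_fruit(
    cube: HyperCube,
    threshold: float = 0.2,
    band_window: tuple | None = None,
) -> np.ndarray:
    """Boolean fruit mask by thresholding mean reflectance, largest component kept.

    ``band_window`` (lo_nm, hi_nm) restricts the bands averaged for the
    threshold image; the default uses all bands. A threshold of 0 yields a
    full-frame mask (reflectance is positive). Raises if nothing exceeds the
    threshold.
    """
    if cube.flavor != "reflectance":
        raise ValueError("segment_fruit expects a reflectance cube")
    keep = np.ones(cube.bands, dtype=bool)
    if band_window is not None:
        keep = (cube.wavelengths >= band_window[0]) & (cube.wavelengths <= band_window[1])
        if not keep.any():
            raise ValueError(f"no bands inside window {band_window}")
    intensity = cube.data[:, :, keep].mean(axis=2)
    mask = intensity > threshold
    if not mask.any():
        raise ValueError(f"no pixel exceeds the segmentation threshold {threshold}")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def predict_pixels(
    cube: HyperCube,
    model: LSSVMModel,
    band_selection_nm: np.ndarray,
    mask: np.ndarray,
    tol_nm: float = 2.0,
) -> SSCMap:
    """Predict SSC for every masked pixel at the selected wavelengths.

    Each requested wavelength is matched to the nearest cube band; a
    mismatch beyond ``tol_nm`` raises an error listing the offending
    wavelengths. The model must have been trained on spectra at exactly
    these wavelengths (same count and order).
    """
    if cube.flavor != "reflectance":
        raise ValueError("predict_pixels expects a reflectance cube")
    band_selection_nm = np.asarray(band_selection_nm, dtype=float)
    if band_selection_nm.size != model.Xtrain.shape[1]:
        raise ValueError(
            f"model was trained on {model.Xtrain.shape[1]} wavelengths, "
            f"{band_selection_nm.size} requested"
        )
    idx = np.abs(cube.wavelengths[None, :] - band_selection_nm[:, None]).argmin(axis=1)
    offsets = np.abs(cube.wavelengths[idx] - band_selection_nm)
    if np.any(offsets > tol_nm):
        bad = band_selection_nm[offsets > tol_nm]
        raise ValueError(
            f"no cube band within {tol_nm} nm of requested wavelengths: "
            + ", ".join(f"{w:.1f}" for w in bad)
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cube.lines, cube.samples):
        raise ValueError("mask shape does not match the cube's spatial extent")

    spectra = cube.data[mask][:, idx]
    values = np.full((cube.lines, cube.samples), np.nan)
    values[mask] = predict(model, spectra)
    return SSCMap(values=values, mask=mask)


def render_map(sscmap: SSCMap, out_path: str, dpi: int = 100) -> str:
    """Write the SSC map as a PNG with a blue-to-red 0-60 % colorbar.

    Values outside the scale are clipped to the end colors for display only.
    Encoder settings are fixed so identical maps render byte-identically.
    """
    lo, hi = sscmap.scale
    fig, ax = plt.subplots(figsize=(5, 4))
    shown = np.ma.masked_invalid(sscmap.values)
    im = ax.imshow(shown, cmap="jet", vmin=lo, vmax=hi, interpolation="nearest")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("SSC (%)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "hyperssc"})
    plt.close(fig)
    return out_path
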