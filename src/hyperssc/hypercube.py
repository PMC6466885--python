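"""ENVI-style hyperspectral cubes: I/O, reflectance calibration, band cropping, ROI means.

Conventions
-----------
* Cube arrays are ``(lines, samples, bands)`` in memory, row-major, 0-based.
* ROIs are half-open: rows ``[row0, row0 + height)``, columns ``[col0, col0 + width)``.
* Reflectance calibration follows the standard black/white correction
  ``R = (I_r - I_d) / (I_w - I_d)`` with dark frame ``I_d`` and white
  reference ``I_w``.

Only the plain ENVI dialect an InGaAs line-scan camera emits is supported:
a ``key = value`` text header next to a binary raster, interleaves
BIL/BSQ/BIP, data types 4 (float32) and 12 (uint16), little or big endian.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HyperCube",
    "ReferenceFrames",
    "ROISpec",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "crop_bands",
    "extract_roi_mean",
    "center_roi_on_mask",
]

#: ENVI numeric data-type codes accepted by this reader.
_ENVI_DTYPES = {4: np.dtype("float32"), 12: np.dtype("uint16")}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}
_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class HyperCube:
    """A hyperspectral raster with its band-center wavelengths.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Raw digital numbers or relative reflectance.
    wavelengths : ndarray, shape (bands,)
        Band centers in nm, strictly increasing.
    flavor : {"raw", "reflectance"}
        Whether ``data`` holds detector counts or calibrated reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    flavor: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (lines, samples, bands), got {self.data.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.flavor not in ("raw", "reflectance"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """Dark-current and white-reference frames for black/white correction.

    Either full cubes matching the raw image layout (per-pixel, per-band;
    the default acquisition mode) or per-band vectors of spatially averaged
    references.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")
        if self.dark.ndim not in (1, 3):
            raise ValueError("reference frames must be per-band vectors (1-D) or full cubes (3-D)")


@dataclass
class ROISpec:
    """Rectangular region of interest, half-open, 0-based.

    The default 15 x 30 pixel patch is the equatorial sampling window used
    to turn one fruit image into one mean spectrum.
    """

    row0: int
    col0: int
    height: int = 15
    width: int = 30

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _binary_path_for(header_path: str) -> str:
    base = header_path[:-4] if header_path.endswith(".hdr") else header_path
    for cand in (base, base + ".img", base + ".dat", base + ".raw"):
        if os.path.isfile(cand) and os.path.abspath(cand) != os.path.abspath(header_path):
            return cand
    raise FileNotFoundError(f"no binary raster found next to ENVI header {header_path!r}")


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where a value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi(header_path: str) -> HyperCube:
    """Read an ENVI header + binary raster pair into a :class:`HyperCube`.

    Raises a descriptive error for a missing binary file, a wavelength list
    inconsistent with the band count, a raster whose size does not match the
    header dimensions, or an unsupported interleave / data type.
    """
    with open(header_path, "r") as fh:
        fields = _parse_envi_header(fh.read())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r} (supported: {_INTERLEAVES})")
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code} (supported: {sorted(_ENVI_DTYPES)})")
    dtype = _ENVI_DTYPES[code]
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength list")
    wl_text = fields["wavelength"].strip()
    if wl_text.startswith("{"):
        wl_text = wl_text[1:-1]
    wavelengths = np.array([float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    binary_path = _binary_path_for(header_path)
    raw = np.fromfile(binary_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"binary raster {binary_path!r} holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    return HyperCube(np.ascontiguousarray(data), wavelengths, flavor="raw")


def write_envi(cube: HyperCube, header_path: str, interleave: str = "bil") -> str:
    """Write ``cube`` as an ENVI header + ``.img`` raster pair.

    Returns the binary raster path. The on-disk dtype is the cube array's
    dtype (must be uint16 or float32).
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _ENVI_CODES:
        raise ValueError(f"cube dtype {dtype} not writable as ENVI (use uint16 or float32)")

    base = header_path[:-4] if header_path.endswith(".hdr") else header_path
    binary_path = base + ".img"
    if interleave == "bip":
        disk = cube.data
    elif interleave == "bil":
        disk = cube.data.transpose(0, 2, 1)
    else:
        disk = cube.data.transpose(2, 0, 1)
    np.ascontiguousarray(disk).tofile(binary_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hyperssc export}\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        "wavelength = {\n " + wl + "\n}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    return binary_path


# ---------------------------------------------------------------------------
# Calibration and spectral extraction
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Black/white correction: ``R = (I_r - I_d) / (I_w - I_d)``.

    ``refs`` may be full frames matching the raw cube or per-band vectors.
    Every used location must satisfy ``white - dark > 0``; the first
    violation is reported by its index.
    """
    if raw.flavor != "raw":
        raise ValueError("calibrate_reflectance expects a raw-flavor cube")
    dark, white = refs.dark, refs.white
    if dark.ndim == 3 and dark.shape != raw.data.shape:
        raise ValueError(
            f"reference frame shape {dark.shape} does not match cube shape {raw.data.shape}"
        )
    if dark.ndim == 1 and dark.shape[0] != raw.bands:
        raise ValueError(
            f"per-band reference length {dark.shape[0]} does not match band count {raw.bands}"
        )
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        loc = np.unravel_index(np.argmax(bad), bad.shape)
        raise ValueError(f"white - dark is non-positive at location {tuple(int(i) for i in loc)}")
    refl = (raw.data.astype(float) - dark) / denom
    return HyperCube(refl, raw.wavelengths.copy(), flavor="reflectance")


def crop_bands(cube: HyperCube, lo_nm: float, hi_nm: float) -> HyperCube:
    """Keep the bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got [{lo_nm}, {hi_nm}]")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands fall inside [{lo_nm}, {hi_nm}] nm")
    return HyperCube(cube.data[:, :, keep], cube.wavelengths[keep], flavor=cube.flavor)


def extract_roi_mean(cube: HyperCube, roi: ROISpec) -> np.ndarray:
    """Per-band arithmetic mean spectrum over a rectangular ROI.

    The cube must be reflectance flavor (one fruit patch -> one spectrum).
    """
    if cube.flavor != "reflectance":
        raise ValueError("extract_roi_mean expects a reflectance cube")
    r1, c1 = roi.row0 + roi.height, roi.col0 + roi.width
    if r1 > cube.lines or c1 > cube.samples:
        raise ValueError(
            f"ROI rows [{roi.row0},{r1}) x cols [{roi.col0},{c1}) exceeds "
            f"cube extent {cube.lines} x {cube.samples}"
        )
    patch = cube.data[roi.row0:r1, roi.col0:c1, :]
    return patch.reshape(-1, cube.bands).mean(axis=0)


def center_roi_on_mask(mask: np.ndarray, height: int = 15, width: int = 30) -> ROISpec:
    """Convenience: an ROI centered on the centroid of a boolean fruit mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.nonzero(mask)
    r0 = int(round(rows.mean() - height / 2))
    c0 = int(round(cols.mean() - width / 2))
    r0 = min(max(r0, 0), mask.shape[0] - height)
    c0 = min(max(c0, 0), mask.shape[1] - width)
    return ROISpec(r0, c0, height, width)
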