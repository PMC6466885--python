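"""Synthetic jujube NIR data with the spectral and compositional structure the analysis assumes.

No public hyperspectral jujube accession exists, so this module generates
stand-in data whose *statistical* structure matches the study design:

* four maturity stages (immature, white-mature, crisp-mature, full-mature)
  whose soluble-solids content (SSC, %) follows truncated normals with the
  published per-stage mean / SD / min / max (13.61 +/- 2.55 in [9.1, 17.8],
  19.85 +/- 1.35 in [16.0, 22.9], 27.30 +/- 3.96 in [18.8, 37.6],
  35.94 +/- 3.33 in [24.2, 44.0]), 150 samples per stage by default;
* 256-band reflectance spectra over 900-1700 nm with water-related
  absorption dips near 980, 1224 and 1450 nm and an SSC-proportional
  reflectance decline over the 1377-1672 nm sensitive window (higher SSC =>
  lower reflectance), flat in-band noise, and amplified noise outside
  950-1675 nm so that band cropping is a meaningful step;
* small fruit-shaped raw-DN cubes with dark/white reference frames (so the
  black/white calibration path is exercised end to end) and a smooth,
  asymmetric per-pixel SSC field as ground truth for map-recovery tests.

The generator is a measurement-free phenomenological model: Gaussian dips
on a flat baseline, a linear SSC-reflectance link, i.i.d. Gaussian noise.
It deliberately omits scattering effects, baseline drift between sessions,
and any nonlinearity of the SSC signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

from .dataset import STAGES, SpectralDataset
from .hypercube import HyperCube, ReferenceFrames

__all__ = [
    "StagePrior",
    "SpectralModel",
    "SyntheticTruth",
    "STAGE_PRIORS",
    "sample_ssc",
    "generate_spectrum",
    "generate_cube",
    "generate_dataset",
]


@dataclass(frozen=True)
class StagePrior:
    """Truncated-normal SSC prior for one maturity stage (all values in %)."""

    stage: str
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float

    def __post_init__(self) -> None:
        if not self.min_pct <= self.mean_pct <= self.max_pct:
            raise ValueError("prior mean must lie inside [min, max]")
        if self.sd_pct <= 0:
            raise ValueError("prior sd must be positive")


#: Published per-stage SSC statistics (total-sample rows): mean, SD, min, max in %.
STAGE_PRIORS: dict[str, StagePrior] = {
    "immature": StagePrior("immature", 13.61, 2.55, 9.1, 17.8),
    "white_mature": StagePrior("white_mature", 19.85, 1.35, 16.0, 22.9),
    "crisp_mature": StagePrior("crisp_mature", 27.30, 3.96, 18.8, 37.6),
    "full_mature": StagePrior("full_mature", 35.94, 3.33, 24.2, 44.0),
}


@dataclass
class SpectralModel:
    """Phenomenological NIR reflectance model for jujube flesh.

    Reflectance at SSC ``s`` (%) and wavelength ``lam`` (nm):

        R(lam) = baseline - sum_k depth_k * exp(-(lam - c_k)^2 / (2 w_k^2))
                 - s * |sensitivity| * taper(lam) + noise(lam)

    ``taper`` is a trapezoid that is 1 deep inside the sensitive window and
    ramps to 0 just *outside* its edges, so the SSC effect is strictly
    negative at every band within the window. Noise is i.i.d. Gaussian with
    sd ``noise_sd`` inside the low-noise band and ``edge_noise_mult`` times
    that outside it (mimicking detector roll-off at the spectral edges).
    """

    n_bands: int = 256
    lo_nm: float = 900.0
    hi_nm: float = 1700.0
    baseline: float = 0.85
    #: (center nm, Gaussian sd nm, depth) of the water-related absorption dips
    absorption_features: tuple = (
        (980.0, 22.0, 0.12),
        (1224.0, 28.0, 0.08),
        (1450.0, 34.0, 0.22),
    )
    #: reflectance decrease per % SSC inside the sensitive window (negative)
    ssc_sensitivity: float = -0.004
    sensitive_window: tuple = (1377.0, 1672.0)
    window_ramp_nm: float = 25.0
    noise_sd: float = 0.002
    edge_noise_mult: float = 6.0
    #: low-noise band retained by the cropping step
    keep_window: tuple = (950.0, 1675.0)

    def __post_init__(self) -> None:
        if self.ssc_sensitivity >= 0:
            raise ValueError("ssc_sensitivity must be negative (higher SSC => lower reflectance)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.lo_nm, self.hi_nm, self.n_bands)

    def sensitivity_profile(self) -> np.ndarray:
        """Per-band SSC sensitivity (reflectance units per % SSC, <= 0)."""
        lam = self.wavelengths
        lo, hi = self.sensitive_window
        r = self.window_ramp_nm
        up = np.clip((lam - (lo - r)) / (2 * r), 0.0, 1.0)
        down = np.clip(((hi + r) - lam) / (2 * r), 0.0, 1.0)
        return self.ssc_sensitivity * up * down

    def noise_profile(self) -> np.ndarray:
        lam = self.wavelengths
        inside = (lam >= self.keep_window[0]) & (lam <= self.keep_window[1])
        return np.where(inside, self.noise_sd, self.noise_sd * self.edge_noise_mult)

    def clean_spectra(self, ssc_pct: np.ndarray) -> np.ndarray:
        """Noiseless reflectance spectra for a vector of SSC values."""
        lam = self.wavelengths
        dips = np.zeros_like(lam)
        for center, width, depth in self.absorption_features:
            dips += depth * np.exp(-((lam - center) ** 2) / (2 * width**2))
        base = self.baseline - dips
        return base[None, :] + np.outer(np.asarray(ssc_pct, float), self.sensitivity_profile())


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated cube: sample SSC, pixel field, mask."""

    ssc_pct: float
    pixel_field: np.ndarray  # 2-D, NaN outside the mask
    mask: np.ndarray  # 2-D boolean


def sample_ssc(prior: StagePrior, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` SSC values (%) from the stage prior, truncated to [min, max]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if prior.min_pct == prior.max_pct:
        raise ValueError("degenerate prior: min == max with positive sd")
    a = (prior.min_pct - prior.mean_pct) / prior.sd_pct
    b = (prior.max_pct - prior.mean_pct) / prior.sd_pct
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=prior.mean_pct, scale=prior.sd_pct, size=n, random_state=rng)


def generate_spectrum(ssc_pct: float, model: SpectralModel | None = None, seed: int = 0) -> np.ndarray:
    """One reflectance spectrum at the given SSC (%, must be within 0-60)."""
    model = model or SpectralModel()
    if not 0.0 <= ssc_pct <= 60.0:
        raise ValueError(f"ssc_pct must be in [0, 60], got {ssc_pct}")
    rng = np.random.default_rng(seed)
    clean = model.clean_spectra(np.array([ssc_pct]))[0]
    noisy = clean + rng.standard_normal(model.n_bands) * model.noise_profile()
    return np.clip(noisy, 1e-3, 1.19)


def generate_cube(
    ssc_mean: float,
    shape: tuple[int, int] = (48, 48),
    model: SpectralModel | None = None,
    heterogeneity_sd: float = 1.5,
    seed: int = 0,
    smooth_sigma: float = 3.0,
    dark_level: float = 0.05,
    white_level: float = 0.90,
) -> tuple[HyperCube, ReferenceFrames, SyntheticTruth]:
    """A fruit-shaped raw-DN cube plus reference frames and ground truth.

    An elliptical fruit mask is placed on a dark background. The per-pixel
    SSC field is smoothed white noise plus a linear gradient (guaranteeing
    the asymmetric, non-uniform within-fruit variation seen in real fruit),
    rescaled so its masked mean is exactly ``ssc_mean`` and its masked sd is
    ``heterogeneity_sd``. Raw digital numbers encode reflectance as
    ``DN = R * (white - dark) + dark`` with constant reference frames, so
    black/white calibration recovers the reflectance exactly.
    """
    model = model or SpectralModel()
    lines, samples = shape
    if lines < 16 or samples < 16:
        raise ValueError("cube shape must be at least 16 x 16")
    rng = np.random.default_rng(seed)

    rr, cc = np.mgrid[0:lines, 0:samples]
    r0, c0 = (lines - 1) / 2, (samples - 1) / 2
    mask = ((rr - r0) / (0.38 * lines)) ** 2 + ((cc - c0) / (0.42 * samples)) ** 2 <= 1.0

    field = np.full(shape, np.nan)
    if heterogeneity_sd > 0:
        z = gaussian_filter(rng.standard_normal(shape), smooth_sigma)
        z = z + 0.8 * (cc / samples) + 0.4 * (rr / lines)  # asymmetry by construction
        zm = z[mask]
        z = (z - zm.mean()) / zm.std()
        field[mask] = np.clip(ssc_mean + heterogeneity_sd * z[mask], 0.0, 60.0)
    else:
        field[mask] = ssc_mean

    refl = np.empty((lines, samples, model.n_bands))
    noise = rng.standard_normal(refl.shape) * model.noise_profile()
    refl[mask] = model.clean_spectra(field[mask])
    refl[~mask] = 0.05  # dark background
    refl = np.clip(refl + noise, 1e-3, 1.19)

    dark = np.full(refl.shape, dark_level)
    white = np.full(refl.shape, white_level)
    dn = (refl * (white - dark) + dark).astype(np.float32)
    cube = HyperCube(dn, model.wavelengths, flavor="raw")
    return cube, ReferenceFrames(dark=dark, white=white), SyntheticTruth(ssc_mean, field, mask)


def generate_dataset(
    n_per_stage: int = 150,
    model: SpectralModel | None = None,
    seed: int = 0,
) -> SpectralDataset:
    """Mean spectra + reference SSC for four maturity stages.

    Default sizes reproduce the study design: 150 samples per stage,
    600 in total.
    """
    if n_per_stage < 10:
        raise ValueError("n_per_stage must be >= 10")
    model = model or SpectralModel()
    rng = np.random.default_rng(seed)
    X_parts, y_parts, stage_parts, id_parts = [], [], [], []
    for stage in STAGES:
        prior = STAGE_PRIORS[stage]
        ssc = sample_ssc(prior, n_per_stage, seed=int(rng.integers(2**31 - 1)))
        clean = model.clean_spectra(ssc)
        noise = rng.standard_normal(clean.shape) * model.noise_profile()
        X_parts.append(np.clip(clean + noise, 1e-3, 1.19))
        y_parts.append(ssc)
        stage_parts.append(np.repeat(stage, n_per_stage))
        id_parts.append(np.array([f"{stage}-{i:03d}" for i in range(n_per_stage)]))
    return SpectralDataset(
        X=np.vstack(X_parts),
        wavelengths=model.wavelengths,
        y=np.concatenate(y_parts),
        stage=np.concatenate(stage_parts),
        ids=np.concatenate(id_parts),
    )
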