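"""Synthetic breast-DWI cohort generator.

Produces labelled two-b-value DWI cases whose region-level ADC statistics
carry the structure the downstream pipeline is built to detect:

* per-region mean ADC ascending from the tumour core to the distal stroma,
  with the whole-tumour mean centred near 0.888e-3 mm^2/s;
* group-specific correlation between per-case region means — adjacent-only
  coupling in the low-Ki-67 group, longer-range (AR(1)-like) coupling in the
  high-Ki-67 group;
* a positively skewed ADC component at the tumour boundary of high-Ki-67
  cases (gamma-distributed, mean-centred, so only the shape of the boundary
  histogram changes).

Geometry is deliberately simple: a circular tumour inside an elliptical
fibroglandular support surrounded by fat, on a 2-D slice.  Pixel ADC within
a rendering band is the band's latent mean plus i.i.d. Gaussian noise, so
the configured correlation matrix is the only inter-region coupling.  The
two images are rendered from the ground-truth ADC map via the
mono-exponential decay s1 = s0 * exp(-(b1-b0) * ADC), which the mapping
stage inverts exactly when ``noise_sd = 0``.

All ADC-valued configuration is in units of 1e-3 mm^2/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .segmentation import REGION_NAMES, signed_edge_distance

#: margin (px) a tumour edge must keep from the image border: the boundary
#: half-width plus three 4-px shells, plus 2 px of slack
REQUIRED_MARGIN_PX = 2 + 3 * 4 + 2

_FAT_ADC = 0.35  # 1e-3 mm^2/s, static fat signal
_TISSUE_S0 = 200.0
_FAT_S0 = 60.0
_S0_TEXTURE_SD = 4.0


def _tridiagonal_corr(r: float) -> np.ndarray:
    m = np.eye(6)
    idx = np.arange(5)
    m[idx, idx + 1] = m[idx + 1, idx] = r
    return m


def default_corr_low() -> np.ndarray:
    """Adjacent-region coupling only (first off-diagonal band, r = 0.5)."""
    return _tridiagonal_corr(0.5)


def default_corr_high() -> np.ndarray:
    """AR(1)-type coupling (rho = 0.7): adjacent plus longer-range bands."""
    return toeplitz(0.7 ** np.arange(6))


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults define the reference study conditions.

    ``region_mean_profile_*`` and ``region_sd`` are 6-vectors ordered
    (S_I, S_T, S_B, S_P, S_M, S_D); ``boundary_skew_high`` is the gamma scale
    (1e-3 mm^2/s, shape fixed at 2) of the mean-centred skew component added
    to boundary pixels of high-Ki-67 cases.

    ``noise_sd`` is the median per-pixel noise SD; each case draws its own
    SD as ``noise_sd`` times a lognormal factor with log-SD ``noise_sd_cv``.
    Without that case-level heterogeneity every dispersion statistic would be
    nearly deterministic given the region size, which no real cohort shows.
    """

    n_cases: int = 80
    high_fraction: float = 0.66
    image_shape: tuple[int, int] = (96, 96)
    pixel_spacing_mm: float = 1.45
    tumour_radius_px_range: tuple[int, int] = (10, 16)
    region_mean_profile_low: tuple[float, ...] = (0.84, 0.91, 1.08, 1.30, 1.50, 1.62)
    region_mean_profile_high: tuple[float, ...] = (0.80, 0.87, 1.00, 1.18, 1.40, 1.58)
    region_sd: tuple[float, ...] = (0.15,) * 6
    region_corr_low: np.ndarray = field(default_factory=default_corr_low)
    region_corr_high: np.ndarray = field(default_factory=default_corr_high)
    boundary_skew_high: float = 0.12
    noise_sd: float = 0.12
    noise_sd_cv: float = 0.25
    b0: float = 50.0
    b1: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.high_fraction <= 1:
            raise ValueError("high_fraction must lie in [0, 1]")
        if self.boundary_skew_high < 0 or self.noise_sd < 0 or self.noise_sd_cv < 0:
            raise ValueError(
                "boundary_skew_high, noise_sd and noise_sd_cv must be >= 0"
            )
        lo, hi = self.tumour_radius_px_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid tumour_radius_px_range")
        if hi + REQUIRED_MARGIN_PX > (min(self.image_shape) - 1) / 2:
            raise ValueError(
                f"tumour radius up to {hi} px leaves no room for the stromal "
                f"shells ({REQUIRED_MARGIN_PX} px margin) in an image of "
                f"shape {self.image_shape}"
            )
        for profile in (self.region_mean_profile_low, self.region_mean_profile_high):
            p = np.asarray(profile, dtype=float)
            if p.shape != (6,) or np.any(np.diff(p) < 0):
                raise ValueError(
                    "region mean profiles must be nondecreasing 6-vectors "
                    "(tumour core to distal stroma)"
                )
        for corr in (self.region_corr_low, self.region_corr_high):
            c = np.asarray(corr, dtype=float)
            if c.shape != (6, 6) or not np.allclose(c, c.T):
                raise ValueError("correlation matrices must be symmetric 6x6")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrices must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrices must be positive semidefinite")
        band = np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
        if np.any(np.asarray(self.region_corr_low)[band > 1] != 0):
            raise ValueError(
                "region_corr_low may couple adjacent regions only "
                "(first off-diagonal band)"
            )


@dataclass(frozen=True)
class SyntheticCase:
    """One rendered case: two DWI images, tumour mask and ground truth."""

    case_id: str
    ki67_label: str
    s0_image: np.ndarray = field(repr=False)
    s1_image: np.ndarray = field(repr=False)
    tumour_mask: np.ndarray = field(repr=False)
    ground_truth_region_means: np.ndarray = field(repr=False)
    ground_truth_adc: np.ndarray = field(repr=False)
    fibroglandular_truth: np.ndarray = field(repr=False)


def _disc(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def _ellipse(
    shape: tuple[int, int], centre: tuple[float, float], semi: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - centre[0]) / semi[0]) ** 2 + ((cc - centre[1]) / semi[1]) ** 2 <= 1.0


def generate_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Render ``config.n_cases`` labelled cases, deterministic given the seed.

    Exactly ``round(high_fraction * n_cases)`` cases are labelled high, in a
    seed-determined order.  Per case, the 6-vector of latent region means is
    drawn from the group's multivariate normal (mean profile, SDs,
    correlation matrix); pixels of each rendering band get the band's latent
    mean plus i.i.d. Gaussian noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    n_high = round(config.high_fraction * config.n_cases)
    labels = np.array(["high"] * n_high + ["low"] * (config.n_cases - n_high))
    rng.shuffle(labels)

    sd = np.asarray(config.region_sd, dtype=float)
    cov = {
        "low": sd[:, None] * np.asarray(config.region_corr_low) * sd[None, :],
        "high": sd[:, None] * np.asarray(config.region_corr_high) * sd[None, :],
    }
    profile = {
        "low": np.asarray(config.region_mean_profile_low, dtype=float),
        "high": np.asarray(config.region_mean_profile_high, dtype=float),
    }

    cases = []
    for i, label in enumerate(labels):
        cases.append(
            _render_case(f"case_{i:03d}", label, profile[label], cov[label], config, rng)
        )
    return cases


def _render_case(
    case_id: str,
    label: str,
    mean_profile: np.ndarray,
    cov: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SyntheticCase:
    shape = config.image_shape
    lo, hi = config.tumour_radius_px_range
    radius = int(rng.integers(lo, hi + 1))
    margin = radius + REQUIRED_MARGIN_PX
    centre = (
        rng.uniform(margin, shape[0] - 1 - margin),
        rng.uniform(margin, shape[1] - 1 - margin),
    )
    tumour = _disc(shape, centre, radius)
    fibro = _ellipse(
        shape,
        (centre[0] + rng.uniform(-3, 3), centre[1] + rng.uniform(-3, 3)),
        (
            (radius + REQUIRED_MARGIN_PX) * rng.uniform(1.05, 1.25),
            (radius + REQUIRED_MARGIN_PX) * rng.uniform(1.05, 1.25),
        ),
    )
    fibro |= tumour

    latent = rng.multivariate_normal(mean_profile, cov)  # 1e-3 mm^2/s
    latent = np.maximum(latent, 0.05)  # ADC cannot be negative

    # disjoint rendering bands by signed distance from the tumour edge; the
    # latent S_T mean is bookkept as ground truth but the rendered tumour is
    # the core/boundary mixture (see methods note)
    d = signed_edge_distance(tumour)
    bands = {
        "S_I": d <= -2,
        "S_B": (d > -2) & (d <= 2),
        "S_P": (d > 2) & (d <= 6),
        "S_M": (d > 6) & (d <= 10),
        "S_D": (d > 10) & (d <= 14),
    }
    adc = np.full(shape, _FAT_ADC)
    adc[fibro] = latent[REGION_NAMES.index("S_D")]  # far stroma plateau
    for name, band in bands.items():
        adc[band] = latent[REGION_NAMES.index(name)]
    case_noise_sd = config.noise_sd * (
        rng.lognormal(0.0, config.noise_sd_cv) if config.noise_sd_cv > 0 else 1.0
    )
    adc += rng.normal(0.0, case_noise_sd, size=shape)
    if label == "high" and config.boundary_skew_high > 0:
        band = bands["S_B"]
        skew = rng.gamma(2.0, config.boundary_skew_high, size=int(band.sum()))
        adc[band] += skew - 2.0 * config.boundary_skew_high
    adc = np.maximum(adc, 1e-4)  # keep signal decay well defined

    s0 = np.where(fibro, _TISSUE_S0, _FAT_S0) + rng.normal(
        0.0, _S0_TEXTURE_SD, size=shape
    )
    s0 = np.maximum(s0, 1.0)
    s1 = s0 * np.exp(-(config.b1 - config.b0) * adc * 1e-3)

    return SyntheticCase(
        case_id=case_id,
        ki67_label=str(label),
        s0_image=s0,
        s1_image=s1,
        tumour_mask=tumour,
        ground_truth_region_means=latent,
        ground_truth_adc=adc * 1e-3,  # mm^2/s
        fibroglandular_truth=fibro,
    )


# ---------------------------------------------------------------------------
# disk round-trip


def _save_nifti(array: np.ndarray, spacing_mm: float, path: Path) -> None:
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_case(case: SyntheticCase, directory: str | Path, spacing_mm: float = 1.45) -> dict:
    """Write one case (NIfTI images + mask, JSON ground truth); returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "s0_path": directory / f"{case.case_id}_b0.nii.gz",
        "s1_path": directory / f"{case.case_id}_b1.nii.gz",
        "mask_path": directory / f"{case.case_id}_mask.nii.gz",
    }
    _save_nifti(case.s0_image, spacing_mm, paths["s0_path"])
    _save_nifti(case.s1_image, spacing_mm, paths["s1_path"])
    _save_nifti(case.tumour_mask.astype(np.float64), spacing_mm, paths["mask_path"])
    truth_path = directory / f"{case.case_id}_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "case_id": case.case_id,
                "ki67_label": case.ki67_label,
                "region_means_1e-3_mm2_s": dict(
                    zip(REGION_NAMES, map(float, case.ground_truth_region_means))
                ),
            },
            indent=2,
        )
    )
    paths["truth_path"] = truth_path
    return {k: str(v) for k, v in paths.items()}


def write_cohort(
    cases: list[SyntheticCase], directory: str | Path, spacing_mm: float = 1.45
) -> Path:
    """Write all cases plus a CSV manifest (case_id, label, file paths)."""
    directory = Path(directory)
    rows = []
    for case in cases:
        paths = write_case(case, directory, spacing_mm)
        rows.append({"case_id": case.case_id, "ki67_label": case.ki67_label, **paths})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_nifti(path: str | Path) -> np.ndarray:
    """Load a (possibly singleton-padded) NIfTI volume as a 2-D array."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return np.squeeze(data)


def read_manifest(manifest: str | Path) -> pd.DataFrame:
    table = pd.read_csv(manifest)
    required = {"case_id", "ki67_label", "s0_path", "s1_path", "mask_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return table
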