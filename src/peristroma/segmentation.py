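"""Fibroglandular segmentation and six-region tumour/stroma decomposition.

Fibroglandular (non-fatty) breast tissue is segmented on the low-b DWI image
with fuzzy C-means clustering on pixel intensity; the brighter cluster is
tissue, the darker fat.  Each case is then decomposed, by signed Euclidean
distance ``d`` from the tumour edge (negative inside the tumour), into six
regions:

======  =====================================  =====================
name    definition                             notes
======  =====================================  =====================
S_I     d <= -2                                inner tumour
S_T     tumour mask                            whole tumour
S_B     -2 <= d <= 2                           boundary band
S_P     2 < d <= 6, fibroglandular             proximal stromal shell
S_M     6 < d <= 10, fibroglandular            middle stromal shell
S_D     10 < d <= 14, fibroglandular           distal stromal shell
======  =====================================  =====================

Each stromal shell is 4 px wide; at the default 1.45 mm pixel spacing that is
5.8 mm of stroma per shell.  Interval endpoints for S_I and S_B are closed,
so the d = -2 contour belongs to both; the regions are analysed
independently downstream, so the overlap is harmless.  Only the stromal
shells are clipped by the fibroglandular mask — the boundary band
intentionally contains tumour pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

REGION_NAMES = ("S_I", "S_T", "S_B", "S_P", "S_M", "S_D")

#: integer labels used when a RegionSet is serialised to a label volume
REGION_LABELS = {name: i + 1 for i, name in enumerate(REGION_NAMES)}


class DegenerateImageError(ValueError):
    """Raised when an image cannot support intensity clustering."""


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy C-means parameters (defaults: 2 clusters, fuzzifier 2)."""

    n_clusters: int = 2
    fuzzifier: float = 2.0
    tolerance: float = 1e-5
    max_iterations: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


def fuzzy_c_means(
    values: np.ndarray, config: FCMConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Standard fuzzy C-means on a 1-D sample of scalar values.

    Memberships are initialised uniformly at random from ``config.seed`` and
    the membership/centroid updates iterated until the objective decreases by
    less than ``tolerance`` (or ``max_iterations``).  Returns
    ``(centroids, memberships)`` with ``memberships`` of shape
    ``(n_values, n_clusters)`` summing to 1 along axis 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateImageError("constant or empty image")
    c, m = config.n_clusters, config.fuzzifier
    rng = np.random.default_rng(config.seed)
    u = rng.random((x.size, c))
    u /= u.sum(axis=1, keepdims=True)

    prev_obj = np.inf
    for _ in range(config.max_iterations):
        w = u**m
        centroids = (w.T @ x) / w.sum(axis=0)
        d2 = (x[:, None] - centroids[None, :]) ** 2
        obj = float((w * d2).sum())
        # membership update: u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1));
        # a pixel exactly on a centroid gets full membership there
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        if prev_obj - obj < config.tolerance:
            break
        prev_obj = obj
    return centroids, u


def segment_fibroglandular(
    b50_image: np.ndarray, config: FCMConfig | None = None
) -> np.ndarray:
    """Fibroglandular-tissue mask from the b=50 image, excluding fat.

    Pixels are assigned to their highest-membership cluster (ties to the
    lower-index cluster); the mask is the set assigned to the cluster with
    the highest centroid intensity, i.e. the bright parenchyma.
    """
    config = config or FCMConfig()
    image = np.asarray(b50_image, dtype=float)
    centroids, u = fuzzy_c_means(image.ravel(), config)
    assigned = np.argmax(u, axis=1)  # argmax takes the first (lowest) index on ties
    bright = int(np.argmax(centroids))
    return (assigned == bright).reshape(image.shape)


@dataclass(frozen=True)
class RegionSet:
    """The six binary region masks for one case."""

    masks: dict[str, np.ndarray] = field(repr=False)
    pixel_spacing_mm: float = 1.45
    empty_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = set(REGION_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"missing region masks: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def to_label_image(self) -> np.ndarray:
        """Single integer label image (overlaps resolved in S_I..S_D order).

        Lossy where regions overlap (S_I/S_B at the d=-2 contour, S_T over
        both); intended for visualisation and file export.
        """
        out = np.zeros(self.masks["S_T"].shape, dtype=np.int16)
        for name in REGION_NAMES:
            out[self.masks[name] & (out == 0)] = REGION_LABELS[name]
        return out


def signed_edge_distance(tumour_mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (px) from the tumour edge, negative inside.

    Outside pixels carry the distance to the nearest tumour pixel centre;
    inside pixels minus the distance to the nearest background pixel centre.
    """
    mask = np.asarray(tumour_mask, dtype=bool)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return outside - inside


def build_regions(
    tumour_mask: np.ndarray,
    fibroglandular_mask: np.ndarray,
    shell_px: int = 4,
    boundary_halfwidth_px: int = 2,
    pixel_spacing_mm: float = 1.45,
) -> RegionSet:
    """Decompose a case into the six regions by distance from the tumour edge.

    If the tumour mask has several connected components only the largest is
    kept (with a warning).  Regions that come out empty — a tumour thinner
    than twice the boundary half-width, or stromal shells wiped out by the
    fibroglandular intersection — are flagged in ``empty_regions`` so that
    downstream feature extraction records them as missing.
    """
    tumour = np.asarray(tumour_mask, dtype=bool)
    fibro = np.asarray(fibroglandular_mask, dtype=bool)
    if tumour.shape != fibro.shape:
        raise ValueError("tumour and fibroglandular masks differ in shape")
    if not tumour.any():
        raise ValueError("tumour mask is empty")

    labelled, n_comp = ndimage.label(tumour)
    if n_comp > 1:
        warnings.warn(
            f"tumour mask has {n_comp} components; keeping the largest",
            stacklevel=2,
        )
        sizes = ndimage.sum_labels(tumour, labelled, index=range(1, n_comp + 1))
        tumour = labelled == (int(np.argmax(sizes)) + 1)

    h = boundary_halfwidth_px
    outer = h + 3 * shell_px
    d = signed_edge_distance(tumour)
    edge_rows, edge_cols = np.nonzero((d > 0) & (d <= outer))
    if (
        edge_rows.size
        and (
            edge_rows.min() == 0
            or edge_cols.min() == 0
            or edge_rows.max() == tumour.shape[0] - 1
            or edge_cols.max() == tumour.shape[1] - 1
        )
    ):
        raise ValueError(
            f"stromal shells (out to {outer} px from the tumour edge) do not "
            "fit inside the image"
        )

    masks = {
        "S_I": d <= -h,
        "S_T": tumour,
        "S_B": (d >= -h) & (d <= h),
        "S_P": (d > h) & (d <= h + shell_px) & fibro,
        "S_M": (d > h + shell_px) & (d <= h + 2 * shell_px) & fibro,
        "S_D": (d > h + 2 * shell_px) & (d <= outer) & fibro,
    }
    empty = tuple(name for name in REGION_NAMES if not masks[name].any())
    for name in empty:
        warnings.warn(f"region {name} is empty", stacklevel=2)
    return RegionSet(
        masks=masks, pixel_spacing_mm=pixel_spacing_mm, empty_regions=empty
    )
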