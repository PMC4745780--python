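"""CAF cohort segmentation and growth analysis.

Fluorescent cohort signal is low-contrast and intensity-variant over time, so
a single global (e.g. Otsu) threshold fails; instead the threshold is local:
each pixel is compared against the Gaussian-weighted mean of its
(2k+1) x (2k+1) neighborhood,

    T(x, y) = sum_{i,j} f(x - i, y - j) w(i, j),
    w(i, j) proportional to exp(-(i^2 + j^2) / sigma^2),

with the weights normalized to unit sum so that T is a weighted local mean.
A pixel is foreground iff p(x, y) - kappa > T(x, y) (ties -> background):
the constant kappa acts as a noise margin applied on the pixel side, so a
positive kappa suppresses flat background and increasing kappa never adds
foreground pixels. Components
are 8-connected throughout; small noisy regions are removed. Cohort growth is
the total foreground pixel count per frame, normalized to the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .config import AdaptiveThresholdConfig
from .io import MaskSequence

__all__ = [
    "CohortRegion",
    "gaussian_kernel",
    "adaptive_threshold",
    "clean_mask",
    "extract_cohorts",
    "fibroblast_area_series",
    "growth_rate_series",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class CohortRegion:
    """One connected CAF cluster: outer contour, area and bounding box."""

    label: int
    contour: np.ndarray            # (N, 2) closed (y, x) boundary vertices
    area: int                      # component pixel count
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


def gaussian_kernel(k: int, sigma: float) -> np.ndarray:
    """(2k+1) x (2k+1) kernel w(i,j) ~ exp(-(i^2+j^2)/sigma^2), unit sum."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    idx = np.arange(-k, k + 1, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    w = np.exp(-(ii ** 2 + jj ** 2) / sigma ** 2)
    return w / w.sum()


def adaptive_threshold(img: np.ndarray,
                       params: AdaptiveThresholdConfig | None = None) -> np.ndarray:
    """Local adaptive threshold: foreground iff p - kappa > local Gaussian mean.

    Borders are handled by mirror reflection. Returns a boolean mask.
    """
    params = params or AdaptiveThresholdConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("adaptive_threshold expects a single-channel image")
    w = gaussian_kernel(params.block_halfwidth, params.sigma_value)
    local_mean = ndi.correlate(img, w, mode="reflect")
    return (img - params.kappa) > local_mean


def clean_mask(mask: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_area`` pixels."""
    mask = np.asarray(mask).astype(bool)
    if min_area <= 1:
        return mask.copy()
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def extract_cohorts(mask: np.ndarray) -> list[CohortRegion]:
    """One CohortRegion per 8-connected component of a cleaned mask.

    The outer contour is traced at sub-pixel level 0.5 on a zero-padded copy
    so components touching the border still yield a closed boundary; contour
    coordinates are clipped back into the image frame.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    regions: list[CohortRegion] = []
    h, w = mask.shape
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        ys, xs = np.nonzero(comp)
        bbox = (int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        outer = max(contours, key=len) - 1.0  # undo padding offset
        outer[:, 0] = np.clip(outer[:, 0], 0, h - 1)
        outer[:, 1] = np.clip(outer[:, 1], 0, w - 1)
        regions.append(CohortRegion(lab, outer, area, bbox))
    return regions


def fibroblast_area_series(masks: MaskSequence) -> np.ndarray:
    """Total foreground pixels per frame (fibroblast-covered area)."""
    return np.array([int(m.sum()) for m in masks.frames], dtype=float)


def growth_rate_series(area_series: np.ndarray) -> np.ndarray:
    """Growth rate: current area / initial area; element 0 is exactly 1."""
    a = np.asarray(area_series, dtype=float)
    if a.size == 0:
        raise ValueError("empty area series")
    if a[0] <= 0:
        raise ValueError("initial area must be > 0 for growth normalization")
    out = a / a[0]
    out[0] = 1.0
    return out


def segment_sequence(seq, params: AdaptiveThresholdConfig | None = None,
                     denoise: bool = True) -> MaskSequence:
    """Full fluorescence-channel segmentation: (median + NLM) -> adaptive
    threshold -> small-region removal -> fill enclosed holes, per frame.

    Cohort area is the region enclosed by the traced outer cluster boundary,
    so interior pixels the local threshold misses (flat bright cores whose
    whole neighborhood is equally bright) are restored by hole filling.
    """
    from .preprocess import median_filter, nlm_denoise

    params = params or AdaptiveThresholdConfig()
    out = []
    for f in seq.frames:
        g = np.asarray(f, dtype=np.float64)
        if denoise:
            g = median_filter(g)
            g = nlm_denoise(g)
        m = adaptive_threshold(g, params)
        m = ndi.binary_fill_holes(clean_mask(m, params.min_area))
        out.append(m)
    return MaskSequence(out, source_channel=seq.channel)
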