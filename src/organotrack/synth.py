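"""Synthetic phantoms with exact ground truth.

Emulates the statistical structure of fluorescent co-culture time-lapse data:
bright, branched "fibroblast cohort" blobs and round/protrusive "organoid"
blobs on a granular, noisy background, with known inter-frame jitter, growth,
translation and branch geometry. All generators are fully deterministic under
a fixed seed, and ground-truth areas are the drawn foreground pixel counts.

Contours and coordinates follow the package convention: (row, col) = (y, x),
origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .io import Channel, ImageSequence

__all__ = [
    "PhantomGroundTruth",
    "generate_star_contour",
    "star_notch_depth",
    "generate_cohort_sequence",
    "generate_coculture_sequence",
    "generate_mrf_image",
    "generate_organoid_field",
    "generate_texture",
    "shift_image",
]

_FOREGROUND = 200.0
_BACKGROUND = 20.0


@dataclass
class PhantomGroundTruth:
    """Known truth for a generated phantom sequence."""

    seed: int
    shifts: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    # per consecutive frame pair, (dy, dx) jitter of frame t+1 relative to frame t
    areas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # per-frame true foreground pixel count of the cohort blob
    centroids: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    # per-frame true blob centroid (y, x), including jitter
    branch_count: int = 0
    branch_depth: float = 0.0       # analytic notch depth of the star blob, px
    translation: tuple[float, float] = (0.0, 0.0)  # true (dy, dx) motion per frame
    masks: list[np.ndarray] = field(default_factory=list)  # per-frame true masks
    organoid_areas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    organoid_masks: list[np.ndarray] = field(default_factory=list)


def star_notch_depth(n_points: int, outer_r: float, inner_r: float) -> float:
    """Analytic depth of each concave notch of the star polygon.

    Adjacent outer vertices subtend an angle 2*pi/n at the center, so their
    chord lies at distance outer_r*cos(pi/n) from the center. Each inner
    vertex sits on the bisector at radius inner_r, hence its distance to the
    hull chord is outer_r*cos(pi/n) - inner_r.
    """
    return outer_r * np.cos(np.pi / n_points) - inner_r


def generate_star_contour(n_points: int, outer_r: float, inner_r: float,
                          center: tuple[float, float] = (0.0, 0.0),
                          phase: float = 0.0) -> np.ndarray:
    """Closed star polygon with ``n_points`` concave notches.

    Returns a (2*n_points, 2) array of (y, x) vertices alternating outer and
    inner radius, counter-clockwise in the (x, y) plane. The notch depth is
    :func:`star_notch_depth`.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if not (outer_r > inner_r > 0):
        raise ValueError("require outer_r > inner_r > 0")
    ang = phase + np.arange(2 * n_points) * (np.pi / n_points)
    r = np.where(np.arange(2 * n_points) % 2 == 0, outer_r, inner_r)
    y = center[0] + r * np.sin(ang)
    x = center[1] + r * np.cos(ang)
    return np.stack([y, x], axis=1)


def _granular_background(shape: tuple[int, int], rng: np.random.Generator,
                         strength: float = 0.25, scale: float = 8.0) -> np.ndarray:
    """Low-frequency multiplicative field emulating ECM granularity."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), scale)
    f /= max(np.abs(f).max(), 1e-12)
    return 1.0 + strength * f


def _ecm_texture(shape: tuple[int, int], rng: np.random.Generator,
                 amplitude: float = 15.0, scale: float = 0.5) -> np.ndarray:
    """Sharp static ECM texture (matrix granularity, debris, fixed pattern).

    This texture moves only with camera jitter, never with the cells; its
    broadband static detail is what anchors frame registration in real
    sequences, where most scene content is unchanged between hourly frames.
    """
    t = ndi.gaussian_filter(rng.standard_normal(shape), scale)
    t /= max(np.abs(t).max(), 1e-12)
    return amplitude * t


def _cell_texture(shape: tuple[int, int], rng: np.random.Generator,
                  amplitude: float = 20.0, scale: float = 1.5) -> np.ndarray:
    """Intracellular fluorescence texture; translated with the cells so
    optical flow has signal inside otherwise-uniform cell bodies."""
    t = ndi.gaussian_filter(rng.standard_normal(shape), scale)
    t /= max(np.abs(t).max(), 1e-12)
    return amplitude * t


def _draw_blob(shape: tuple[int, int], contour: np.ndarray) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(contour[:, 0], contour[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def generate_cohort_sequence(
    n_frames: int,
    jitter_amplitude: int = 0,
    growth_per_frame: float = 0.0,
    n_branches: int = 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    motion_per_frame: tuple[float, float] = (0.0, 0.0),
    base_radius: float = 40.0,
    texture_amplitude: float = 15.0,
) -> tuple[ImageSequence, PhantomGroundTruth]:
    """Phantom fluorescence time-lapse of one growing, branched CAF cohort.

    The blob's area grows geometrically by (1 + growth_per_frame) per frame
    (the linear scale grows by its square root), its centroid translates by
    ``motion_per_frame`` (dy, dx), and the whole scene is shifted by integer
    per-frame jitter drawn uniformly from [-jitter_amplitude, jitter_amplitude].
    Additive Gaussian read noise (``noise_sigma``) is applied after the scene
    shift, like camera noise. Ground truth records jitter shifts, drawn pixel
    counts, centroids and branch geometry.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if growth_per_frame < 0:
        raise ValueError("growth_per_frame must be >= 0")
    if n_branches < 0:
        raise ValueError("n_branches must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    center0 = np.array([h / 2.0, w / 2.0])
    bg_field = _granular_background(shape, rng)
    bg_tex = _ecm_texture(shape, rng, texture_amplitude)
    cell_tex0 = _cell_texture(shape, rng)

    # per-pair jitter, integer-valued
    if jitter_amplitude > 0:
        pair_shifts = rng.integers(-jitter_amplitude, jitter_amplitude + 1,
                                   size=(n_frames - 1, 2)).astype(float)
    else:
        pair_shifts = np.zeros((n_frames - 1, 2))
    cum = np.vstack([np.zeros(2), np.cumsum(pair_shifts, axis=0)])

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    areas = np.zeros(n_frames)
    centroids = np.zeros((n_frames, 2))
    depth = 0.0
    for t in range(n_frames):
        scale = (1.0 + growth_per_frame) ** (t / 2.0)
        r_out = base_radius * scale
        center = center0 + np.asarray(motion_per_frame) * t
        total = center + cum[t]
        margin = r_out + 2
        if not (margin <= total[0] <= h - margin and margin <= total[1] <= w - margin):
            raise ValueError(
                "blob would exit the frame; use a larger canvas or smaller "
                "motion/jitter/growth")
        if n_branches > 0:
            r_in = 0.55 * r_out
            contour = generate_star_contour(n_branches, r_out, r_in, center)
            depth = star_notch_depth(n_branches, r_out, r_in)
            clean_mask = _draw_blob(shape, contour)
        else:
            clean_mask = np.zeros(shape, dtype=bool)
            rr, cc = draw_disk(tuple(center), r_out, shape=shape)
            clean_mask[rr, cc] = True
        # cells occlude the matrix: the static ECM texture exists only
        # outside, while the intracellular texture translates with the cell
        offset = np.asarray(motion_per_frame) * t
        if np.allclose(offset, 0):
            cell_tex = cell_tex0
        else:
            cell_tex = ndi.shift(cell_tex0, offset, order=3, mode="grid-wrap")
        clean = np.where(clean_mask, _FOREGROUND + cell_tex,
                         _BACKGROUND * bg_field + bg_tex)
        dy, dx = int(cum[t, 0]), int(cum[t, 1])
        scene = np.roll(clean, (dy, dx), axis=(0, 1))
        true_mask = np.roll(clean_mask, (dy, dx), axis=(0, 1))
        if noise_sigma > 0:
            scene = scene + rng.normal(0, noise_sigma, shape)
        frames.append(scene)
        masks.append(true_mask)
        areas[t] = true_mask.sum()
        ys, xs = np.nonzero(true_mask)
        centroids[t] = (ys.mean(), xs.mean())

    seq = ImageSequence(frames, Channel.fluor_green)
    truth = PhantomGroundTruth(seed=seed, shifts=pair_shifts, areas=areas,
                               centroids=centroids, branch_count=n_branches,
                               branch_depth=depth,
                               translation=tuple(motion_per_frame), masks=masks)
    return seq, truth


def generate_coculture_sequence(
    n_frames: int,
    jitter_amplitude: int = 0,
    growth_per_frame: float = 0.0,
    organoid_growth_per_frame: float = 0.0,
    n_branches: int = 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    motion_per_frame: tuple[float, float] = (0.0, 0.0),
    base_radius: float = 35.0,
    organoid_radius: float = 25.0,
    texture_amplitude: float = 15.0,
) -> tuple[ImageSequence, ImageSequence, PhantomGroundTruth]:
    """Two-channel co-culture phantom: phase (organoid + cohort) and
    fluorescence (cohort only).

    The organoid is a disc in one quadrant growing geometrically by
    ``organoid_growth_per_frame``; the fibroblast cohort occupies the opposite
    quadrant. Both appear in the phase channel; only the cohort fluoresces,
    mirroring GFP-labelled CAFs next to unlabelled organoids.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    caf_center0 = np.array([0.32 * h, 0.32 * w])
    org_center = np.array([0.70 * h, 0.70 * w])
    bg_field = _granular_background(shape, rng)
    bg_tex = _ecm_texture(shape, rng, texture_amplitude)
    cell_tex0 = _cell_texture(shape, rng)
    org_tex = _cell_texture(shape, rng)

    if jitter_amplitude > 0:
        pair_shifts = rng.integers(-jitter_amplitude, jitter_amplitude + 1,
                                   size=(n_frames - 1, 2)).astype(float)
    else:
        pair_shifts = np.zeros((n_frames - 1, 2))
    cum = np.vstack([np.zeros(2), np.cumsum(pair_shifts, axis=0)])

    phase_frames, fluor_frames = [], []
    masks, org_masks = [], []
    areas = np.zeros(n_frames)
    org_areas = np.zeros(n_frames)
    centroids = np.zeros((n_frames, 2))
    depth = 0.0
    for t in range(n_frames):
        scale = (1.0 + growth_per_frame) ** (t / 2.0)
        r_out = base_radius * scale
        caf_center = caf_center0 + np.asarray(motion_per_frame) * t
        margin = r_out + 2
        total = caf_center + cum[t]
        if not (margin <= total[0] <= h - margin and margin <= total[1] <= w - margin):
            raise ValueError("cohort would exit the frame; use a larger canvas")
        if n_branches > 0:
            r_in = 0.55 * r_out
            contour = generate_star_contour(n_branches, r_out, r_in, caf_center)
            depth = star_notch_depth(n_branches, r_out, r_in)
            caf_mask = _draw_blob(shape, contour)
        else:
            caf_mask = np.zeros(shape, dtype=bool)
            rr, cc = draw_disk(tuple(caf_center), r_out, shape=shape)
            caf_mask[rr, cc] = True
        r_org = organoid_radius * (1.0 + organoid_growth_per_frame) ** (t / 2.0)
        if r_org + 2 > min(h - org_center[0], w - org_center[1]):
            raise ValueError("organoid would exit the frame; use a larger canvas")
        org_mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk(tuple(org_center), r_org, shape=shape)
        org_mask[rr, cc] = True

        offset = np.asarray(motion_per_frame) * t
        if np.allclose(offset, 0):
            cell_tex = cell_tex0
        else:
            cell_tex = ndi.shift(cell_tex0, offset, order=3, mode="grid-wrap")
        bg = _BACKGROUND * bg_field + bg_tex
        fluor = np.where(caf_mask, _FOREGROUND + cell_tex, bg)
        phase = np.where(caf_mask, _FOREGROUND + cell_tex,
                         np.where(org_mask, _FOREGROUND + org_tex, bg))
        dy, dx = int(cum[t, 0]), int(cum[t, 1])
        fluor = np.roll(fluor, (dy, dx), axis=(0, 1))
        phase = np.roll(phase, (dy, dx), axis=(0, 1))
        caf_m = np.roll(caf_mask, (dy, dx), axis=(0, 1))
        org_m = np.roll(org_mask, (dy, dx), axis=(0, 1))
        if noise_sigma > 0:
            fluor = fluor + rng.normal(0, noise_sigma, shape)
            phase = phase + rng.normal(0, noise_sigma, shape)
        phase_frames.append(phase)
        fluor_frames.append(fluor)
        masks.append(caf_m)
        org_masks.append(org_m)
        areas[t] = caf_m.sum()
        org_areas[t] = org_m.sum()
        ys, xs = np.nonzero(caf_m)
        centroids[t] = (ys.mean(), xs.mean())

    phase_seq = ImageSequence(phase_frames, Channel.phase)
    fluor_seq = ImageSequence(fluor_frames, Channel.fluor_green)
    truth = PhantomGroundTruth(seed=seed, shifts=pair_shifts, areas=areas,
                               centroids=centroids, branch_count=n_branches,
                               branch_depth=depth,
                               translation=tuple(motion_per_frame), masks=masks,
                               organoid_areas=org_areas, organoid_masks=org_masks)
    return phase_seq, fluor_seq, truth


def generate_mrf_image(shape: tuple[int, int] = (64, 64),
                       label_map: np.ndarray | None = None,
                       means: Sequence[float] = (10.0, 100.0, 200.0),
                       sigmas: Sequence[float] = (5.0, 5.0, 5.0),
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Three-label phantom for MRF segmentation: disc in halo on background.

    Label semantics follow the confocal model: 0 = background, 1 = cell
    shadow (halo), 2 = in-focus cells (disc). Pixel intensities are drawn
    from the Gaussian of the true label.
    """
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if len(np.unique(means)) != 3:
        raise ValueError("means must be 3 distinct values")
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be >= 0")
    h, w = shape
    if label_map is None:
        label_map = np.zeros(shape, dtype=np.int64)
        c = (h / 2.0, w / 2.0)
        r_disc = min(h, w) * 0.22
        r_halo = min(h, w) * 0.36
        rr, cc = draw_disk(c, r_halo, shape=shape)
        label_map[rr, cc] = 1
        rr, cc = draw_disk(c, r_disc, shape=shape)
        label_map[rr, cc] = 2
    else:
        label_map = np.asarray(label_map, dtype=np.int64)
        if label_map.shape != tuple(shape):
            raise ValueError("label_map shape mismatch")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(label_map.shape)
    img = means[label_map] + sigmas[label_map] * noise
    return img, label_map


def generate_organoid_field(
    n_organoids: int,
    roundness_range: tuple[float, float] = (0.95, 1.0),
    appendage_spec: Sequence[tuple[int, float]] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (15.0, 22.0),
    appendage_width: int = 3,
    max_retries: int = 200,
) -> tuple[np.ndarray, list[dict]]:
    """Field of non-overlapping organoid discs with optional thin appendages.

    ``appendage_spec`` gives (count, length) per organoid (cycled if shorter
    than ``n_organoids``). Returns the fluorescence image and a per-object
    truth list with keys mask/area/centroid/appendage_count/appendage_lengths.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if appendage_spec is None:
        appendage_spec = [(0, 0.0)]
    for _, length in appendage_spec:
        if length >= min(h, w) / 4:
            raise ValueError("appendage length must be < frame size / 4")
    img = np.full(shape, _BACKGROUND, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    truths: list[dict] = []
    for i in range(n_organoids):
        n_app, app_len = appendage_spec[i % len(appendage_spec)]
        r = rng.uniform(*radius_range)
        reach = r + (app_len if n_app else 0) + 4
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(reach, h - reach)
            cx = rng.uniform(reach, w - reach)
            obj = _draw_organoid(shape, (cy, cx), r, n_app, app_len,
                                 appendage_width, rng)
            grown = ndi.binary_dilation(obj, iterations=3)
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"failed to place organoid {i} after {max_retries} retries; "
                "reduce n_organoids or enlarge the canvas")
        occupied |= obj
        img[obj] = _FOREGROUND
        ys, xs = np.nonzero(obj)
        truths.append({
            "mask": obj,
            "area": int(obj.sum()),
            "centroid": (ys.mean(), xs.mean()),
            "appendage_count": int(n_app),
            "appendage_lengths": [float(app_len)] * int(n_app),
        })
    img = img + rng.normal(0, 2.0, shape)
    return img, truths


def _draw_organoid(shape, center, radius, n_app, app_len, width, rng):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    if n_app:
        ang0 = rng.uniform(0, 2 * np.pi)
        for k in range(n_app):
            ang = ang0 + 2 * np.pi * k / n_app
            d = np.array([np.sin(ang), np.cos(ang)])
            # thin bar from the disc edge, protruding app_len beyond it
            for s in np.arange(0, app_len + 0.5, 0.5):
                p = np.asarray(center) + d * (radius - 1 + s)
                rr, cc = draw_disk(tuple(p), width / 2.0 + 0.5, shape=shape)
                mask[rr, cc] = True
    return mask


def generate_texture(shape: tuple[int, int], seed: int = 0,
                     smooth_sigma: float = 3.0,
                     contrast: float = 50.0, offset: float = 100.0) -> np.ndarray:
    """Smooth random texture (band-limited noise) for registration/flow tests."""
    rng = np.random.default_rng(seed)
    t = ndi.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    t /= max(np.abs(t).max(), 1e-12)
    return offset + contrast * t


def shift_image(img: np.ndarray, shift: tuple[float, float],
                circular: bool = True) -> np.ndarray:
    """Shift image content by (dy, dx); integer shifts use exact circular roll,
    fractional shifts use spline interpolation with mirror boundaries."""
    dy, dx = shift
    if circular and float(dy).is_integer() and float(dx).is_integer():
        return np.roll(img, (int(dy), int(dx)), axis=(0, 1))
    return ndi.shift(img, (dy, dx), order=3, mode="mirror")
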