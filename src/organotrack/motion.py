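"""CAF motility by dense optical flow (Farnebäck polynomial expansion).

Individual-cell tracking is unreliable in noisy fluorescent co-culture
sequences, so motion is quantified densely: every pixel neighborhood is
approximated by a quadratic polynomial

    f1(x) = x^T A1 x + b1^T x + c1,

and a displacement d of the surface, f2(x) = f1(x - d), implies

    A2 = A1,  b2 = b1 - 2 A1 d  =>  d = -1/2 A1^{-1} (b2 - b1).

The practical estimator averages the pointwise normal equations over a
window, iterates with warping, and refines coarse-to-fine over an image
pyramid. Motility per frame is the mean displacement magnitude over the
segmentation-mask foreground (background suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import FlowConfig
from .io import ImageSequence, MaskSequence

__all__ = [
    "PolyExpansion",
    "FlowField",
    "poly_expansion",
    "farneback_flow",
    "mean_motion_per_frame",
    "motion_series",
]


@dataclass
class PolyExpansion:
    """Per-pixel quadratic coefficients f(x) ~ x^T A x + b^T x + c.

    ``A`` has shape (H, W, 2, 2) (symmetric), ``b`` (H, W, 2) in (y, x)
    order, ``c`` (H, W).
    """

    A: np.ndarray
    b: np.ndarray
    c: np.ndarray


@dataclass
class FlowField:
    """Per-pixel displacement (pixels / frame interval), (dy, dx) components."""

    dy: np.ndarray
    dx: np.ndarray
    valid: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)


def poly_expansion(img: np.ndarray, poly_n: int = 5,
                   poly_sigma: float = 1.1) -> PolyExpansion:
    """Weighted least-squares quadratic fit around every pixel.

    Uses a Gaussian applicability of width ``poly_sigma`` on a
    ``poly_n`` x ``poly_n`` window; the normal-equation matrix G is constant
    over the image, so the fit reduces to six correlations.
    """
    img = np.asarray(img, dtype=np.float64)
    m = poly_n // 2
    idx = np.arange(-m, m + 1, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")  # y, x offsets
    w = np.exp(-(ii ** 2 + jj ** 2) / (2.0 * poly_sigma ** 2))
    basis = np.stack([np.ones_like(ii), ii, jj, ii ** 2, jj ** 2, ii * jj])
    G = np.einsum("kij,lij->kl", basis * w, basis)
    Ginv = np.linalg.inv(G)
    corr = np.stack([ndi.correlate(img, w * basis[k], mode="reflect")
                     for k in range(6)], axis=-1)
    r = corr @ Ginv.T  # (H, W, 6): c, by, bx, ayy, axx, ayx
    c = r[..., 0]
    b = r[..., 1:3]
    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = r[..., 5] / 2.0
    return PolyExpansion(A, b, c)


def _warp_field(field: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Sample ``field`` (H, W, ...) at x + d(x), bilinear, edge-clamped."""
    h, w = field.shape[:2]
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [np.clip(yy + d[..., 0], 0, h - 1), np.clip(xx + d[..., 1], 0, w - 1)]
    if field.ndim == 2:
        return ndi.map_coordinates(field, coords, order=1, mode="nearest")
    flat = field.reshape(h, w, -1)
    out = np.stack([ndi.map_coordinates(flat[..., k], coords, order=1,
                                        mode="nearest")
                    for k in range(flat.shape[-1])], axis=-1)
    return out.reshape(field.shape)


def _flow_level(e1: PolyExpansion, e2: PolyExpansion, d0: np.ndarray,
                window: int, iterations: int,
                reg: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    d = d0.copy()
    for _ in range(iterations):
        A2w = _warp_field(e2.A, d)
        b2w = _warp_field(e2.b, d)
        A = 0.5 * (e1.A + A2w)
        db = -0.5 * (b2w - e1.b) + np.einsum("...ij,...j->...i", A, d)
        # windowed normal equations: G = sum w A^T A, h = sum w A^T db
        AtA = np.einsum("...ki,...kj->...ij", A, A)
        Atb = np.einsum("...ki,...k->...i", A, db)
        G = np.empty_like(AtA)
        hvec = np.empty_like(Atb)
        for i in range(2):
            hvec[..., i] = ndi.uniform_filter(Atb[..., i], window, mode="reflect")
            for j in range(2):
                G[..., i, j] = ndi.uniform_filter(AtA[..., i, j], window,
                                                  mode="reflect")
        det = (G[..., 0, 0] + reg) * (G[..., 1, 1] + reg) - G[..., 0, 1] ** 2
        valid = det > 10 * reg ** 2
        det = np.where(det == 0, 1.0, det)
        d = np.empty_like(d0)
        d[..., 0] = ((G[..., 1, 1] + reg) * hvec[..., 0]
                     - G[..., 0, 1] * hvec[..., 1]) / det
        d[..., 1] = ((G[..., 0, 0] + reg) * hvec[..., 1]
                     - G[..., 0, 1] * hvec[..., 0]) / det
    return d, valid


def farneback_flow(frame_a: np.ndarray, frame_b: np.ndarray,
                   levels: int = 3, window: int = 15, iterations: int = 3,
                   poly_n: int = 5, poly_sigma: float = 1.1) -> FlowField:
    """Dense displacement field taking ``frame_a`` onto ``frame_b``.

    Coarse-to-fine over a Gaussian pyramid with ``levels`` levels (factor 2),
    ``iterations`` warping iterations per level. Constant frames yield a zero
    field. Near-singular windowed systems are Tikhonov-regularized.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if np.array_equal(a, b):
        z = np.zeros(a.shape)
        return FlowField(z, z.copy(), np.ones(a.shape, dtype=bool))

    # pyramids, coarsest last; skip levels that would get tiny
    pyr_a, pyr_b = [a], [b]
    for _ in range(levels - 1):
        if min(pyr_a[-1].shape) < 2 * poly_n + 2:
            break
        pyr_a.append(ndi.zoom(ndi.gaussian_filter(pyr_a[-1], 1.0), 0.5, order=1))
        pyr_b.append(ndi.zoom(ndi.gaussian_filter(pyr_b[-1], 1.0), 0.5, order=1))

    d = np.zeros(pyr_a[-1].shape + (2,))
    valid = np.ones(pyr_a[-1].shape, dtype=bool)
    for lev in range(len(pyr_a) - 1, -1, -1):
        la, lb = pyr_a[lev], pyr_b[lev]
        if d.shape[:2] != la.shape:
            d = np.stack([ndi.zoom(2.0 * d[..., k],
                                   np.array(la.shape) / np.array(d.shape[:2]),
                                   order=1) for k in range(2)], axis=-1)
        e1 = poly_expansion(la, poly_n, poly_sigma)
        e2 = poly_expansion(lb, poly_n, poly_sigma)
        d, valid = _flow_level(e1, e2, d, window, iterations)
    return FlowField(d[..., 0], d[..., 1], valid)


def mean_motion_per_frame(flow: FlowField, mask: np.ndarray) -> float:
    """Mean displacement magnitude over mask foreground; 0 for an empty mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != flow.dy.shape:
        raise ValueError("mask shape does not match flow field")
    if not mask.any():
        return 0.0
    return float(flow.magnitude[mask].mean())


def motion_series(seq: ImageSequence, masks: MaskSequence,
                  params: FlowConfig | None = None) -> np.ndarray:
    """Per-frame-pair motility curve: element i is the masked mean motion
    between frames i and i+1 under mask i."""
    params = params or FlowConfig()
    if seq.n_frames < 2:
        raise ValueError("motion analysis requires >= 2 frames")
    if masks.n_frames < seq.n_frames - 1:
        raise ValueError("need a mask for every flow source frame")
    out = np.zeros(seq.n_frames - 1)
    for i in range(seq.n_frames - 1):
        flow = farneback_flow(seq.frames[i], seq.frames[i + 1],
                              params.levels, params.window, params.iterations,
                              params.poly_n, params.poly_sigma)
        out[i] = mean_motion_per_frame(flow, masks.frames[i])
    return out
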