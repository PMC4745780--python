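"""Time-lapse stabilization by phase correlation.

Sequential image capture introduces frame-to-frame camera jitter. A pure
translation model is assumed: for frames f and g related by a translation
Delta, the Fourier transforms satisfy G(u) = exp(-2*pi*i*u.Delta) * F(u), so
the normalized cross-power spectrum

    T(u) = (F . G*) / (|F| . |G|) = exp(2*pi*i*u.Delta)

inverse-transforms to a single peak whose location gives the motion vector.
Compensation shifts every frame against frame 0 and crops to the maximal
rectangle covered by all compensated frames (out-of-field pixels are removed,
never padded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import ImageSequence

__all__ = ["ShiftEstimate", "estimate_shift", "stabilize_sequence",
           "apply_shifts"]

_EPS = np.finfo(np.float64).eps


@dataclass
class ShiftEstimate:
    """Global translation (dy, dx) of frame b relative to frame a.

    ``peak_response`` is the height of the inverse-transform peak, 1.0 for an
    exact circular shift of identical content.
    """

    dy: float
    dx: float
    peak_response: float
    method: str = "standard"

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dy, self.dx])


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(img.astype(np.float64))
    return np.hypot(gy, gx)


def _wrap(idx: int, n: int) -> float:
    return idx - n if idx > n // 2 else idx


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < _EPS:
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(frame_a: np.ndarray, frame_b: np.ndarray,
                   method: str = "standard", subpixel: bool = True,
                   hann_window: bool = True) -> ShiftEstimate:
    """Estimate the global translation taking frame_a onto frame_b.

    ``method='blur_robust'`` runs phase correlation on gradient-magnitude
    images, which is less sensitive to defocus blur than raw intensities.
    ``subpixel`` refines the correlation peak with a separable quadratic fit;
    disabling it returns the integer argmax (exact on integer-jitter
    phantoms). An optional Hann taper suppresses wrap-around edge energy.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2-D")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image: spectrum normalization undefined")
    if method not in ("standard", "blur_robust"):
        raise ValueError(f"unknown method '{method}'")
    if method == "blur_robust":
        a = _gradient_magnitude(a)
        b = _gradient_magnitude(b)
    if hann_window:
        w = _hann2d(a.shape)
        a = (a - a.mean()) * w
        b = (b - b.mean()) * w

    F = np.fft.fft2(a)
    G = np.fft.fft2(b)
    cross = F * np.conj(G)
    # relative spectral floor: frequencies whose cross-power is negligible
    # (e.g. wiped out by defocus blur) are down-weighted instead of being
    # whitened up to unit modulus, which would bury the peak in noise
    mag = np.abs(cross)
    T = cross / (mag + 1e-6 * mag.max() + _EPS)
    r = np.real(np.fft.ifft2(T))

    # G = exp(-2*pi*i*u.Delta) F puts the correlation peak at -Delta (mod N)
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    peak = float(r[iy, ix])
    # coherence-normalized response: 1 iff every retained frequency is
    # phase-aligned at the peak (e.g. identical frames)
    response = peak / max(float(np.mean(np.abs(T))), _EPS)
    ny, nx = r.shape
    dy = -_wrap(int(iy), ny)
    dx = -_wrap(int(ix), nx)

    if subpixel:
        ym, yp = r[(iy - 1) % ny, ix], r[(iy + 1) % ny, ix]
        xm, xp = r[iy, (ix - 1) % nx], r[iy, (ix + 1) % nx]
        dy -= _parabolic_offset(ym, peak, yp)
        dx -= _parabolic_offset(xm, peak, xp)

    return ShiftEstimate(float(dy), float(dx),
                         min(max(response, 0.0), 1.0), method)


def stabilize_sequence(seq: ImageSequence, method: str = "standard",
                       subpixel: bool = True, hann_window: bool = True,
                       ) -> tuple[ImageSequence, tuple[int, int, int, int], list[ShiftEstimate]]:
    """Stabilize a sequence against frame 0 and crop to the common field.

    Per-consecutive-pair shifts are estimated, accumulated against frame 0,
    compensated (spline shift for fractional, exact roll-free slice for
    integer compensation), and the output is cropped to the maximal rectangle
    covered by every compensated frame.

    Returns (stabilized sequence, crop rectangle (top, left, height, width),
    per-pair shift estimates).
    """
    if seq.n_frames < 2:
        raise ValueError("stabilization requires at least 2 frames")
    pair_shifts = [estimate_shift(seq.frames[i], seq.frames[i + 1], method,
                                  subpixel=subpixel, hann_window=hann_window)
                   for i in range(seq.n_frames - 1)]
    out, crop = apply_shifts(seq, pair_shifts)
    return out, crop, pair_shifts


def apply_shifts(seq: ImageSequence, pair_shifts: list[ShiftEstimate],
                 ) -> tuple[ImageSequence, tuple[int, int, int, int]]:
    """Compensate a sequence with precomputed per-pair shifts and crop.

    Lets a registered second channel (e.g. the fluorescence channel) be
    compensated with shifts estimated on the channel with the most static
    content (by default phase contrast).
    """
    if len(pair_shifts) != seq.n_frames - 1:
        raise ValueError("need one shift estimate per consecutive frame pair")
    h, w = seq.shape
    cum = np.vstack([np.zeros(2),
                     np.cumsum([s.vector for s in pair_shifts], axis=0)])
    if np.any(np.abs(cum[:, 0]) > h / 2) or np.any(np.abs(cum[:, 1]) > w / 2):
        raise ValueError("cumulative shift exceeds half the frame; "
                         "field of view lost")

    # compensate: move frame t content by -cum[t]
    comp: list[np.ndarray] = []
    for t, frame in enumerate(seq.frames):
        s = -cum[t]
        if np.allclose(s, np.round(s)):
            comp.append(np.roll(np.asarray(frame, dtype=np.float64),
                                (int(round(s[0])), int(round(s[1]))), axis=(0, 1)))
        else:
            comp.append(ndi.shift(np.asarray(frame, dtype=np.float64), s,
                                  order=1, mode="nearest"))

    # common rectangle covered by every compensated frame: after moving
    # content by s, valid rows are [max(0, s_y), h + min(0, s_y))
    s_all = -cum
    top = int(np.ceil(max(0.0, s_all[:, 0].max())))
    bot = int(np.floor(h + min(0.0, s_all[:, 0].min())))
    left = int(np.ceil(max(0.0, s_all[:, 1].max())))
    right = int(np.floor(w + min(0.0, s_all[:, 1].min())))
    crop = (top, left, bot - top, right - left)
    frames = [f[top:bot, left:right] for f in comp]
    out = ImageSequence(frames, seq.channel, seq.frame_interval, seq.pixel_size)
    return out, crop
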