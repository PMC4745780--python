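"""Tumor organoid segmentation in time-lapse frames.

The phase-contrast channel has low signal-to-noise and high background
clutter, so segmentation uses intensive denoising (two cascaded non-local
means passes followed by mean-shift filtering), adaptive thresholding,
morphological smoothing (closing then opening with a 3-px disc), and
small-region removal. Because the segmentation also picks up fibroblast
cohorts, and the channels are registered after stabilization, the result is
masked with the fibroblast segmentation from the fluorescence channel:
subtraction wins at contact pixels, so organoid and fibroblast masks never
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .config import AdaptiveThresholdConfig, TumorConfig
from .fibro import adaptive_threshold, clean_mask
from .io import ImageSequence, MaskSequence
from .preprocess import NLMParams, tumor_denoise

logger = logging.getLogger("organotrack")

__all__ = ["TumorMaskFrame", "segment_tumor_frame", "tumor_area_series"]


@dataclass
class TumorMaskFrame:
    """Organoid mask for one frame, disjoint from the fibroblast mask."""

    mask: np.ndarray
    excluded_fibro_pixels: int


def _threshold_params(cfg: TumorConfig) -> AdaptiveThresholdConfig:
    return AdaptiveThresholdConfig(block_halfwidth=cfg.block_halfwidth,
                                   sigma=cfg.sigma, kappa=cfg.kappa,
                                   min_area=cfg.min_area)


def segment_tumor_frame(phase_img: np.ndarray, fibro_mask: np.ndarray,
                        config: TumorConfig | None = None,
                        nlm: NLMParams | None = None,
                        denoise: bool = True) -> TumorMaskFrame:
    """Segment organoids in one registered phase-contrast frame.

    Pipeline: tumor_denoise -> adaptive_threshold -> closing+opening (disc,
    ``smooth_radius``) -> remove components < min_area -> zero out pixels
    inside ``fibro_mask``.
    """
    config = config or TumorConfig()
    phase_img = np.asarray(phase_img, dtype=np.float64)
    fibro_mask = np.asarray(fibro_mask).astype(bool)
    if phase_img.shape != fibro_mask.shape:
        raise ValueError(
            f"phase frame {phase_img.shape} and fibroblast mask "
            f"{fibro_mask.shape} shapes differ")
    img = tumor_denoise(phase_img, nlm) if denoise else phase_img
    raw = adaptive_threshold(img, _threshold_params(config))
    se = disk(config.smooth_radius)
    smooth = ndi.binary_opening(ndi.binary_closing(raw, structure=se),
                                structure=se)
    # organoids are solid bodies: keep the region enclosed by the boundary
    smooth = ndi.binary_fill_holes(smooth)
    cleaned = clean_mask(smooth, config.min_area)
    excluded = int(np.count_nonzero(cleaned & fibro_mask))
    return TumorMaskFrame(cleaned & ~fibro_mask, excluded)


def tumor_area_series(seq: ImageSequence, fibro_masks: MaskSequence,
                      config: TumorConfig | None = None,
                      nlm: NLMParams | None = None,
                      denoise: bool = True,
                      collagen_only: bool = False) -> np.ndarray:
    """Per-frame organoid area (pixels), identical fixed parameters throughout.

    ``collagen_only`` sequences are accepted but logged with a warning:
    granular pure-collagen backgrounds segment poorly.
    """
    config = config or TumorConfig()
    if collagen_only:
        logger.warning("collagen-only sequence: tumor segmentation is "
                       "unreliable on granular pure-collagen backgrounds")
    if fibro_masks.n_frames != seq.n_frames:
        raise ValueError("fibroblast masks must cover every frame")
    areas = np.zeros(seq.n_frames)
    for t in range(seq.n_frames):
        res = segment_tumor_frame(seq.frames[t], fibro_masks.frames[t],
                                  config, nlm, denoise=denoise)
        areas[t] = int(res.mask.sum())
    return areas
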