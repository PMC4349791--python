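"""Radiograph denoising and contrast enhancement.

Plain-film spine images are noisy and low-contrast, which hurts both
profile-model training and boundary search.  The pipeline applied here
is a median filter (impulse-noise suppression that preserves bone
edges) followed by contrast-limited adaptive histogram equalization
(CLAHE) on 8x8 tiles, a well-understood stand-in for adaptive
non-linear contrast adjustment.  Both steps can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.exposure import equalize_adapthist

__all__ = ["PreprocessConfig", "denoise", "adaptive_contrast", "preprocess"]


@dataclass
class PreprocessConfig:
    median_window: int = 3  # odd px; 1 disables
    contrast: str = "clahe"  # clahe | gamma | none
    clip: float = 0.01  # CLAHE clip limit, or gamma exponent
    tiles: int = 8  # CLAHE tile grid (tiles x tiles)

    def __post_init__(self):
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median window must be odd and >= 1")
        if self.clip <= 0:
            raise ValueError("contrast strength must be > 0")
        if self.contrast not in ("clahe", "gamma", "none"):
            raise ValueError(f"unknown contrast method {self.contrast!r}")


def denoise(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with edge-replicated borders.

    Each output pixel is the median of its ``window x window``
    neighbourhood; dimensions and the [0, 1] range are preserved.
    """
    img = np.asarray(img, dtype=float)
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if window > min(img.shape):
        raise ValueError("median window larger than image")
    if window == 1:
        return img.copy()
    return median_filter(img, size=window, mode="nearest")


def adaptive_contrast(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast enhancement; output stays in [0, 1], same dimensions.

    Default is CLAHE on an 8x8 tile grid with clip limit 0.01.  A
    constant image is returned unchanged (there is no contrast to
    create from a single gray level).
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]")
    img = np.clip(img, 0.0, 1.0)
    if cfg.contrast == "none" or np.ptp(img) < 1e-12:
        return img.copy()
    if cfg.contrast == "gamma":
        out = img ** cfg.clip
    else:
        kernel = max(8, min(img.shape) // cfg.tiles)
        out = equalize_adapthist(img, kernel_size=kernel, clip_limit=cfg.clip)
    return np.clip(out, 0.0, 1.0)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Denoise then contrast-enhance, per the shared configuration."""
    cfg = cfg or PreprocessConfig()
    return adaptive_contrast(denoise(img, cfg.median_window), cfg)
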