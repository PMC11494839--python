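"""Image preprocessing stack: resize, CLAHE, gamma correction, normalization.

Training images go through the full enhancement path
(resize -> CLAHE -> gamma -> [0,1] normalization); test images are only
resized and normalized.  Masks are always resized with nearest-neighbor
resampling and stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import exposure, transform

from .records import SampleRecord

_CLAHE_NBINS = 256


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing stack.

    ``clahe_clip_limit`` uses the familiar histogram clip factor convention
    (default 2.0); 0 disables CLAHE entirely.  ``gamma`` is the power-law
    exponent (<1 brightens shadows, >1 darkens; 1 is the identity).
    ``apply_enhancement`` selects the training path; the test path skips
    CLAHE and gamma.
    """

    target_size: tuple = (256, 256)
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple = (8, 8)
    gamma: float = 0.8
    apply_enhancement: bool = True

    def __post_init__(self):
        if min(self.target_size) < 8:
            raise ValueError("target_size components must be >= 8")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.clahe_clip_limit < 0:
            raise ValueError("clahe_clip_limit must be >= 0 (0 disables CLAHE)")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid components must be >= 1")


def resize(img: np.ndarray, target) -> np.ndarray:
    """Bilinear resize to (H, W); identity when the size already matches."""
    th, tw = int(target[0]), int(target[1])
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.shape == (th, tw):
        return img.copy()
    return transform.resize(img, (th, tw), order=1, mode="reflect",
                            anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, target) -> np.ndarray:
    """Nearest-neighbor resize of a binary mask; output stays in {0, 1}."""
    th, tw = int(target[0]), int(target[1])
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if mask.shape == (th, tw):
        return mask.copy()
    out = transform.resize(mask, (th, tw), order=0, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def clahe(img: np.ndarray, clip_limit: float = 2.0, tile_grid=(8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image.

    Per-tile histograms are equalized with the excess above the clip
    threshold redistributed, and the per-tile mappings are blended by
    bilinear interpolation.  The clip factor follows the common CLAHE
    convention (~2.0 typical) and is converted internally to the
    normalized scale used by scikit-image (clip / nbins).  A clip of 0
    returns the image unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("clahe expects intensities in [0, 1]")
    if clip_limit < 0:
        raise ValueError("clip_limit must be >= 0")
    rows, cols = int(tile_grid[0]), int(tile_grid[1])
    if rows > img.shape[0] or cols > img.shape[1]:
        raise ValueError("tile grid larger than the image")
    if clip_limit == 0 or img.max() - img.min() < 1e-12:
        # disabled, or a constant image: nothing to equalize
        return img.copy()
    kernel = (max(1, img.shape[0] // rows), max(1, img.shape[1] // cols))
    out = exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=kernel,
                                      clip_limit=clip_limit / _CLAHE_NBINS,
                                      nbins=_CLAHE_NBINS)
    return np.clip(out, 0.0, 1.0)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law intensity transform out = img ** gamma on [0,1] images."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("gamma_correct expects intensities in [0, 1]")
    return np.clip(img, 0.0, 1.0) ** gamma


def normalize(img: np.ndarray, value_range=None) -> np.ndarray:
    """Affine map of the declared (or dtype-inferred) range onto [0, 1].

    Integer dtypes map their full nonnegative range (e.g. uint8: /255).
    Float inputs are assumed already on [0,1] unless a range is declared.
    A degenerate range (hi == lo) maps everything to 0.
    """
    img = np.asarray(img)
    if value_range is None:
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            value_range = (0, info.max)
        else:
            value_range = (0.0, 1.0)
    lo, hi = float(value_range[0]), float(value_range[1])
    if hi == lo:
        return np.zeros_like(img, dtype=np.float64)
    out = (img.astype(np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def preprocess_pipeline(rec: SampleRecord, cfg: PreprocessConfig | None = None
                        ) -> SampleRecord:
    """Apply the full stack to one record, returning a new record.

    Training path: resize -> CLAHE -> gamma -> normalize.  Test path
    (``apply_enhancement=False``): resize -> normalize.  The mask is
    resized with nearest-neighbor resampling and stays binary.
    """
    cfg = cfg or PreprocessConfig()
    img = normalize(rec.image)  # bring integer inputs onto [0,1] first
    img = resize(img, cfg.target_size)
    if cfg.apply_enhancement:
        img = clahe(img, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
        img = gamma_correct(img, cfg.gamma)
    img = normalize(img)
    mask = None if rec.mask is None else resize_mask(rec.mask, cfg.target_size)
    return replace(rec, image=img.astype(np.float32), mask=mask)


def preprocess_manifest(manifest, cfg: PreprocessConfig | None = None):
    from .records import DatasetManifest

    cfg = cfg or PreprocessConfig()
    return DatasetManifest([preprocess_pipeline(r, cfg) for r in manifest],
                           split_tag=manifest.split_tag)
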