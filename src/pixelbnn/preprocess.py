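"""Preprocessing and augmentation of fundus image / vessel mask pairs.

The pipeline mirrors common practice for fundus segmentation: contrast-
limited adaptive histogram equalization (CLAHE) on the full image, a random
crop of 216-256 px per axis, bicubic resize to 256x256, random horizontal/
vertical flips, rotation by 0/90/180 degrees, photometric jitter on the image
only, and finally a remap of 8-bit values into the continuous interval
[-0.5, 0.5] that the network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, exposure, transform

__all__ = [
    "FormatError",
    "ParameterError",
    "FundusImage",
    "VesselMask",
    "ContinuousImage",
    "AugmentConfig",
    "remap_to_continuous",
    "clahe_enhance",
    "resize_pair",
    "augment_pair",
]


class FormatError(ValueError):
    """Raster does not meet the expected channel/value layout."""


class ParameterError(ValueError):
    """Preprocessing parameter incompatible with the image geometry."""


@dataclass
class FundusImage:
    """8-bit RGB fundus photograph with provenance metadata."""

    pixels: np.ndarray
    original_height: int = 0
    original_width: int = 0
    dataset_tag: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"expected HxWx3 image, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.original_height:
            self.original_height = self.pixels.shape[0]
        if not self.original_width:
            self.original_width = self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr, dataset_tag: str = "") -> "FundusImage":
        """Build from an RGB or RGBA raster; any alpha channel is dropped."""
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
        return cls(pixels=arr, dataset_tag=dataset_tag)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class VesselMask:
    """Binary vessel raster: vessel = 1, background = 0."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected HxW mask, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("mask values must be exactly {0, 1}")
        self.pixels = self.pixels.astype(np.uint8)

    @classmethod
    def from_array(cls, arr) -> "VesselMask":
        """Any nonzero pixel maps to vessel (handles {0,255} PNG/GIF masks)."""
        return cls(pixels=(np.asarray(arr) != 0).astype(np.uint8))

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ContinuousImage:
    """Real-valued image with every channel value in [-0.5, 0.5]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"expected HxWx3 image, got shape {self.pixels.shape}")
        if self.pixels.min() < -0.5 - 1e-6 or self.pixels.max() > 0.5 + 1e-6:
            raise FormatError("continuous values must lie in [-0.5, 0.5]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class AugmentConfig:
    crop_min: int = 216
    crop_max: int = 256
    target_size: int = 256
    rotation_angles: tuple[int, ...] = (0, 90, 180)
    brightness_delta_max: float = 0.1
    contrast_factor_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.crop_min > self.crop_max:
            raise ParameterError("crop_min must be <= crop_max")
        if self.target_size <= 0:
            raise ParameterError("target_size must be positive")


#: augmentation profile for 64x64 desk-scale training (same 0.84-1.0 relative
#: crop band as the full-size profile)
SMOKE_AUGMENT = AugmentConfig(crop_min=54, crop_max=64, target_size=64)


def remap_to_continuous(img: FundusImage) -> ContinuousImage:
    """Affinely remap 8-bit channel values from (0, 255) to (-0.5, 0.5)."""
    if not isinstance(img, FundusImage):
        img = FundusImage.from_array(img)
    return ContinuousImage(img.pixels.astype(np.float32) / 255.0 - 0.5)


def continuous_to_uint8(cont: ContinuousImage) -> np.ndarray:
    """Inverse remap (up to quantization)."""
    arr = cont.pixels if isinstance(cont, ContinuousImage) else np.asarray(cont)
    return np.clip(np.round((arr + 0.5) * 255.0), 0, 255).astype(np.uint8)


def clahe_enhance(
    img: FundusImage, clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8)
) -> FundusImage:
    """Contrast-limited adaptive histogram equalization.

    Applied to the lightness channel in CIELAB space so hue is preserved.
    `clip_limit` is in multiples of the mean histogram bin height over a tile
    (the OpenCV convention, default 2.0) and is converted internally to the
    normalized convention of ``skimage.exposure.equalize_adapthist`` assuming
    its 256-bin histograms.
    """
    if not isinstance(img, FundusImage):
        img = FundusImage.from_array(img)
    if clip_limit <= 0:
        raise ParameterError("clip_limit must be > 0")
    h, w = img.pixels.shape[:2]
    th, tw = int(tile_grid[0]), int(tile_grid[1])
    if th < 1 or tw < 1 or h // th < 1 or w // tw < 1:
        raise ParameterError(f"tile grid {tile_grid} too fine for a {h}x{w} image")
    lab = color.rgb2lab(img.pixels)
    lightness = lab[:, :, 0] / 100.0
    equalized = exposure.equalize_adapthist(
        lightness,
        kernel_size=(max(h // th, 1), max(w // tw, 1)),
        clip_limit=clip_limit / 256.0,
    )
    lab[:, :, 0] = equalized * 100.0
    rgb = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    out = np.round(rgb * 255.0).astype(np.uint8)
    return FundusImage(
        out,
        original_height=img.original_height,
        original_width=img.original_width,
        dataset_tag=img.dataset_tag,
    )


def _resize_image(pixels: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    resized = transform.resize(
        pixels.astype(np.float64) / 255.0,
        size_hw,
        order=3,  # bicubic
        mode="reflect",
        anti_aliasing=True,
        preserve_range=False,
    )
    return np.clip(np.round(resized * 255.0), 0, 255).astype(np.uint8)


def _resize_mask(pixels: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    # bicubic on the binary field, then re-binarized at 0.5 to keep thin
    # vessels connected
    resized = transform.resize(
        pixels.astype(np.float64),
        size_hw,
        order=3,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    return (resized > 0.5).astype(np.uint8)


def resize_pair(
    img: FundusImage, mask: VesselMask, size: int
) -> tuple[FundusImage, VesselMask]:
    """Bicubic-resize an image and its mask to size x size; the mask is
    re-binarized by thresholding the interpolated field at 0.5."""
    if size < 1:
        raise ParameterError("size must be >= 1")
    if not isinstance(img, FundusImage):
        img = FundusImage.from_array(img)
    if not isinstance(mask, VesselMask):
        mask = VesselMask.from_array(mask)
    if img.pixels.shape[:2] == (size, size) and mask.pixels.shape == (size, size):
        return img, mask
    out_img = FundusImage(
        _resize_image(img.pixels, (size, size)),
        original_height=img.original_height,
        original_width=img.original_width,
        dataset_tag=img.dataset_tag,
    )
    out_mask = VesselMask(_resize_mask(mask.pixels, (size, size)))
    return out_img, out_mask


def draw_geometry(cfg: AugmentConfig, rng: np.random.Generator, h: int, w: int):
    """Sample one geometric transform: crop (side lengths uniform in
    [crop_min, crop_max] per axis, position uniform over valid placements),
    flip booleans, and a quarter-turn count from the allowed angles."""
    ch = int(rng.integers(cfg.crop_min, cfg.crop_max + 1))
    cw = int(rng.integers(cfg.crop_min, cfg.crop_max + 1))
    if ch > h or cw > w:
        raise ParameterError(f"crop {ch}x{cw} exceeds image bounds {h}x{w}")
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    flip_h = bool(rng.random() < 0.5)
    flip_v = bool(rng.random() < 0.5)
    angle = int(rng.choice(np.asarray(cfg.rotation_angles)))
    return ch, cw, top, left, flip_h, flip_v, angle // 90


def apply_orientation(arr: np.ndarray, flip_h: bool, flip_v: bool, k: int) -> np.ndarray:
    """Horizontal/vertical flips then k quarter-turns; exact (lossless)."""
    if flip_h:
        arr = arr[:, ::-1]
    if flip_v:
        arr = arr[::-1, :]
    if k:
        arr = np.rot90(arr, k)
    return np.ascontiguousarray(arr)


def invert_orientation(arr: np.ndarray, flip_h: bool, flip_v: bool, k: int) -> np.ndarray:
    """Exact inverse of :func:`apply_orientation`."""
    if k:
        arr = np.rot90(arr, -k)
    if flip_v:
        arr = arr[::-1, :]
    if flip_h:
        arr = arr[:, ::-1]
    return np.ascontiguousarray(arr)


def augment_pair(
    img: FundusImage,
    mask: VesselMask,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[ContinuousImage, VesselMask]:
    """One random augmentation draw for an image/mask pair.

    Geometry (crop window, flips, rotation) is shared by image and mask;
    photometric jitter (brightness/contrast) touches the image only. Crop
    side lengths are drawn uniformly from [crop_min, crop_max] independently
    per axis; after the crop both rasters are resized to target_size and the
    image is remapped to continuous space.
    """
    if not isinstance(img, FundusImage):
        img = FundusImage.from_array(img)
    if not isinstance(mask, VesselMask):
        mask = VesselMask.from_array(mask)
    if img.pixels.shape[:2] != mask.pixels.shape:
        raise FormatError("image and mask dimensions differ")
    h, w = img.pixels.shape[:2]
    ch, cw, top, left, flip_h, flip_v, k = draw_geometry(cfg, rng, h, w)
    img_c = img.pixels[top : top + ch, left : left + cw]
    mask_c = mask.pixels[top : top + ch, left : left + cw]

    img_r, mask_r = resize_pair(
        FundusImage(img_c, dataset_tag=img.dataset_tag),
        VesselMask(mask_c),
        cfg.target_size,
    )
    ipx = apply_orientation(img_r.pixels, flip_h, flip_v, k)
    mpx = apply_orientation(mask_r.pixels, flip_h, flip_v, k)

    cont = remap_to_continuous(FundusImage(ipx)).pixels
    delta = rng.uniform(-cfg.brightness_delta_max, cfg.brightness_delta_max)
    factor = rng.uniform(*cfg.contrast_factor_range)
    mean = cont.mean()
    cont = np.clip(mean + (cont - mean) * factor + delta, -0.5, 0.5)
    return ContinuousImage(cont), VesselMask(np.ascontiguousarray(mpx))
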