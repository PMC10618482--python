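"""Deterministic preprocessing of image/mask pairs.

Raw micrographs (typically 3000x2500) are resized to a 16-divisible target
(default 2048x1664, bilinear for pixels / nearest-neighbour for labels),
min-max normalized to [0, 1] per image, and expanded six-fold by a fixed
set of invertible geometric augmentations.  Ground-truth masks are aligned
to the feature grid by 16x16 blockwise majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rescale as _sk_rescale

from .image import AnnotatedImage
from .labels import N_CLASSES

__all__ = [
    "PreprocessConfig",
    "AugmentationSet",
    "DEFAULT_AUGMENTATIONS",
    "resize_pair",
    "normalize",
    "augment_pair",
    "downsample_mask",
]

DOWNSAMPLE_FACTOR = 16


@dataclass(frozen=True)
class PreprocessConfig:
    """Resize/normalize settings. ``target_size=None`` keeps the input size."""

    target_size: tuple[int, int] | None = (2048, 1664)
    image_interpolation: str = "bilinear"
    mask_interpolation: str = "nearest"
    normalize_mode: str = "minmax"

    def __post_init__(self) -> None:
        if self.target_size is not None:
            h, w = self.target_size
            if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
                raise ValueError(f"target dims must be divisible by {DOWNSAMPLE_FACTOR}")
        if self.image_interpolation != "bilinear":
            raise ValueError("only bilinear image interpolation is supported")
        if self.mask_interpolation != "nearest":
            raise ValueError("only nearest-neighbour mask interpolation is supported")
        if self.normalize_mode != "minmax":
            raise ValueError("only minmax normalization is supported")


def resize_pair(image: AnnotatedImage, config: PreprocessConfig) -> AnnotatedImage:
    """Resample pixels bilinearly and the mask by nearest neighbour.

    Nearest-neighbour resampling can only select existing labels, so the
    output mask's label set is a subset of the input's.
    """
    if image.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if config.target_size is None or config.target_size == image.spatial_shape:
        return image.copy()
    h, w = config.target_size
    out_shape = (h, w) if image.pixels.ndim == 2 else (h, w, image.pixels.shape[2])
    px = _sk_resize(
        image.pixels.astype(np.float64),
        out_shape,
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(np.float32)
    mask = None
    if image.mask is not None:
        mask = _sk_resize(
            image.mask, (h, w), order=0, preserve_range=True, anti_aliasing=False
        ).astype(np.uint8)
    return AnnotatedImage(pixels=px, mask=mask, meta=dict(image.meta))


def normalize(image: AnnotatedImage) -> AnnotatedImage:
    """Min-max normalize pixels to [0, 1]; a constant image maps to zeros."""
    px = np.asarray(image.pixels, dtype=np.float64)
    if not np.isfinite(px).all():
        raise ValueError("pixels contain NaN or Inf")
    lo, hi = px.min(), px.max()
    if hi > lo:
        px = (px - lo) / (hi - lo)
    else:
        px = np.zeros_like(px)
    return AnnotatedImage(
        pixels=px.astype(np.float32),
        mask=None if image.mask is None else image.mask.copy(),
        meta=dict(image.meta),
    )


def _pad_to_square(arr: np.ndarray, fill: float) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[:2]
    s = max(h, w)
    py, px = s - h, s - w
    pad = [(py // 2, py - py // 2), (px // 2, px - px // 2)]
    if arr.ndim == 3:
        pad.append((0, 0))
    return np.pad(arr, pad, mode="constant", constant_values=fill), (pad[0][0], pad[1][0])


def _center_crop(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape[:2]
    th, tw = shape
    oy, ox = (h - th) // 2, (w - tw) // 2
    return arr[oy : oy + th, ox : ox + tw]


def _rot_square(arr: np.ndarray, k: int, shape: tuple[int, int], fill: float) -> np.ndarray:
    """Right-angle rotation on the padded square, centre-cropped back."""
    sq, _ = _pad_to_square(arr, fill)
    return np.ascontiguousarray(_center_crop(np.rot90(sq, k), shape))


def _scale_jitter(arr: np.ndarray, order: int, zoom: float = 1.1) -> np.ndarray:
    """Zoom in place by a fixed factor and crop back to the input size."""
    shape = arr.shape[:2]
    channel_axis = 2 if arr.ndim == 3 else None
    big = _sk_rescale(
        arr.astype(np.float64),
        zoom,
        order=order,
        preserve_range=True,
        anti_aliasing=False,
        channel_axis=channel_axis,
    )
    return _center_crop(big, shape)


class AugmentationSet:
    """The fixed set of 6 deterministic geometric augmentations.

    Three right-angle rotations, horizontal and vertical flips, and one
    scale jitter (zoom in place, recropped), applied identically to pixels
    and mask so each input pair yields exactly 6 output pairs of the input
    size — matching a 64-image training pool expanding to 384.
    """

    names = ("rot90", "rot180", "rot270", "hflip", "vflip", "scale")

    def __len__(self) -> int:
        return 6

    def apply(self, image: AnnotatedImage, name: str) -> AnnotatedImage:
        px, mask = image.pixels, image.mask
        shape = image.spatial_shape
        bg = float(np.median(px))  # pad fill for rotated rectangles
        if name == "rot90":
            new_px = _rot_square(px, 1, shape, bg)
            new_mask = None if mask is None else _rot_square(mask, 1, shape, 0)
        elif name == "rot180":
            new_px = np.ascontiguousarray(np.rot90(px, 2))
            new_mask = None if mask is None else np.ascontiguousarray(np.rot90(mask, 2))
        elif name == "rot270":
            new_px = _rot_square(px, 3, shape, bg)
            new_mask = None if mask is None else _rot_square(mask, 3, shape, 0)
        elif name == "hflip":
            new_px = np.ascontiguousarray(px[:, ::-1])
            new_mask = None if mask is None else np.ascontiguousarray(mask[:, ::-1])
        elif name == "vflip":
            new_px = np.ascontiguousarray(px[::-1])
            new_mask = None if mask is None else np.ascontiguousarray(mask[::-1])
        elif name == "scale":
            new_px = _scale_jitter(px, order=1)
            new_mask = None if mask is None else _scale_jitter(mask, order=0)
        else:
            raise KeyError(name)
        meta = dict(image.meta)
        meta["augmentation"] = name
        return AnnotatedImage(
            pixels=np.asarray(new_px, dtype=np.float32),
            mask=None if new_mask is None else np.asarray(new_mask).astype(np.uint8),
            meta=meta,
        )


DEFAULT_AUGMENTATIONS = AugmentationSet()


def augment_pair(
    image: AnnotatedImage, aug: AugmentationSet = DEFAULT_AUGMENTATIONS
) -> list[AnnotatedImage]:
    """Apply every transform in ``aug`` to the pair; returns 6 new pairs."""
    if image.mask is None:
        raise ValueError("augment_pair requires a mask-bearing image")
    return [aug.apply(image, name) for name in aug.names]


def downsample_mask(mask: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Blockwise majority vote of labels onto the feature grid.

    Each ``factor``×``factor`` block maps to its majority label among 1..8;
    label 0 (unannotated) is ignored in the vote, ties break to the lowest
    class index, and a block that is entirely 0 stays 0.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if h % factor or w % factor:
        raise ValueError(f"mask dims {mask.shape} not divisible by {factor}")
    hb, wb = h // factor, w // factor
    blocks = mask.reshape(hb, factor, wb, factor).transpose(0, 2, 1, 3).reshape(hb, wb, -1)
    counts = np.stack(
        [(blocks == lbl).sum(axis=2) for lbl in range(1, N_CLASSES + 1)], axis=2
    )
    out = (np.argmax(counts, axis=2) + 1).astype(np.uint8)
    out[counts.sum(axis=2) == 0] = 0
    return out
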