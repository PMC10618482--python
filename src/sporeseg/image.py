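"""The AnnotatedImage container: a micrograph plus optional per-pixel labels."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .labels import N_CLASSES

__all__ = ["AnnotatedImage"]


@dataclass
class AnnotatedImage:
    """A grayscale (H, W) or RGB (H, W, 3) image with an optional label mask.

    ``pixels`` is a float array, in [0, 1] once normalized.  ``mask`` is an
    integer (H, W) array with values in {0} ∪ {1..8}; 0 marks unannotated
    pixels, which every training and scoring routine ignores.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise ValueError("3-D pixels must have 1 or 3 channels")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.spatial_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != image shape {self.spatial_shape}"
                )
            if self.mask.min() < 0 or self.mask.max() > N_CLASSES:
                raise ValueError("mask values must lie in {0..8}")
            self.mask = self.mask.astype(np.uint8)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def has_mask(self) -> bool:
        return self.mask is not None

    def copy(self) -> "AnnotatedImage":
        return replace(
            self,
            pixels=self.pixels.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )

    def as_rgb(self) -> np.ndarray:
        """Return pixels replicated to 3 channels (float32)."""
        px = self.pixels.astype(np.float32)
        if px.ndim == 2:
            return np.repeat(px[:, :, None], 3, axis=2)
        if px.shape[2] == 1:
            return np.repeat(px, 3, axis=2)
        return px
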