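"""Layer-area quantification of segmentation maps.

For each segmented spore, the relative areas of coat, core and cortex are
reported as fractions of the spore body — all cells classified into the six
spore classes (coat, core, cortex, exosporium, interspace, nap), excluding
background and Badreg.  An alternative denominator restricted to
coat+core+cortex is available.  Group summaries (mean, SD, n) support the
chemical-damage comparison: a model trained on intact spores reads damaged
cores/inner cortices as enlarged cores, so the predicted core ratio rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import SegmentationMap
from .labels import COAT, CORE, CORTEX, SPORE_BODY_CLASSES

__all__ = ["LayerRatios", "GroupSummary", "layer_ratios", "summarize_groups", "ratios_table"]


@dataclass(frozen=True)
class LayerRatios:
    coat_ratio: float
    core_ratio: float
    cortex_ratio: float
    spore_pixel_count: int
    image_id: str = ""

    def __post_init__(self) -> None:
        for name in ("coat_ratio", "core_ratio", "cortex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.coat_ratio + self.core_ratio + self.cortex_ratio > 1.0 + 1e-9:
            raise ValueError("coat+core+cortex ratios cannot exceed 1")
        if self.spore_pixel_count <= 0:
            raise ValueError("spore_pixel_count must be positive")


def layer_ratios(
    segmap: SegmentationMap,
    image_id: str = "",
    denominator: str = "spore_body",
) -> LayerRatios:
    """Relative coat/core/cortex areas within the predicted spore body.

    ``denominator`` is ``"spore_body"`` (all six spore classes, default) or
    ``"ccc"`` (coat+core+cortex only).
    """
    labels = segmap.labels
    if denominator == "spore_body":
        denom_classes = SPORE_BODY_CLASSES
    elif denominator == "ccc":
        denom_classes = (COAT, CORE, CORTEX)
    else:
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    denom = int(np.isin(labels, denom_classes).sum())
    if denom == 0:
        raise ValueError("no spore pixels in the segmentation map (no spore detected)")
    return LayerRatios(
        coat_ratio=float((labels == COAT).sum() / denom),
        core_ratio=float((labels == CORE).sum() / denom),
        cortex_ratio=float((labels == CORTEX).sum() / denom),
        spore_pixel_count=denom,
        image_id=image_id,
    )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    coat_mean: float
    coat_sd: float
    core_mean: float
    core_sd: float
    cortex_mean: float
    cortex_sd: float


def summarize_groups(ratios_by_group: dict[str, list[LayerRatios]]) -> list[GroupSummary]:
    """Per-group mean/SD/n of the three ratios (population SD, ddof=0)."""
    out = []
    for group, ratios in ratios_by_group.items():
        if not ratios:
            raise ValueError(f"group {group!r} is empty")
        arr = np.array([[r.coat_ratio, r.core_ratio, r.cortex_ratio] for r in ratios])
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=0)
        out.append(
            GroupSummary(
                group=group,
                n=len(ratios),
                coat_mean=float(mean[0]),
                coat_sd=float(sd[0]),
                core_mean=float(mean[1]),
                core_sd=float(sd[1]),
                cortex_mean=float(mean[2]),
                cortex_sd=float(sd[2]),
            )
        )
    return out


def ratios_table(ratios_by_group: dict[str, list[LayerRatios]]) -> pd.DataFrame:
    """Long-form table of per-image ratios, one row per image."""
    rows = []
    for group, ratios in ratios_by_group.items():
        for r in ratios:
            rows.append(
                {
                    "image_id": r.image_id,
                    "group": group,
                    "coat_ratio": r.coat_ratio,
                    "core_ratio": r.core_ratio,
                    "cortex_ratio": r.cortex_ratio,
                    "spore_pixel_count": r.spore_pixel_count,
                }
            )
    return pd.DataFrame(rows)
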