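"""Model/Results surface over the hybrid training pipeline.

`SporeLayerSegmenter` is constructed from annotated images plus the
encoder/forest configurations; `fit()` runs the full cross-validated
protocol and returns a `SegmenterResults` carrying the trained hybrid,
per-fold training diagnostics, and evaluation / quantification / plotting
helpers, in the spirit of a statsmodels model-results pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn_features import CNNConfig
from .evaluate import MetricsReport
from .forest import RFConfig, SegmentationMap
from .image import AnnotatedImage
from .labels import DEFAULT_SCHEME
from .pipeline import (
    FoldSplit,
    HybridModel,
    evaluate_hybrid,
    make_folds,
    train_hybrid,
)
from .preprocess import PreprocessConfig
from .quantify import LayerRatios, layer_ratios

__all__ = ["SporeLayerSegmenter", "SegmenterResults"]


class SporeLayerSegmenter:
    """Hybrid CNN + random-forest segmenter of spore layers.

    Parameters
    ----------
    images:
        Mask-bearing training pool.
    cnn_config, rf_config, preprocess:
        Component configurations; defaults follow the reference protocol
        (15-conv/5-pool encoder, 300 trees, 25 candidate features per split).
    k:
        Number of cross-validation folds for encoder checkpointing.
    augment:
        Whether to expand each fold's training items with the 6 geometric
        augmentations.
    """

    def __init__(
        self,
        images: list[AnnotatedImage],
        cnn_config: CNNConfig | None = None,
        rf_config: RFConfig | None = None,
        preprocess: PreprocessConfig | None = None,
        k: int = 3,
        augment: bool = True,
        seed: int = 0,
    ):
        if not images:
            raise ValueError("need at least one training image")
        self.images = images
        self.cnn_config = cnn_config or CNNConfig(seed=seed)
        self.rf_config = rf_config or RFConfig(seed=seed)
        self.preprocess = preprocess or PreprocessConfig(target_size=None)
        self.k = k
        self.augment = augment
        self.seed = seed

    def fit(self, folds: FoldSplit | None = None) -> "SegmenterResults":
        folds = folds or make_folds(list(range(len(self.images))), k=self.k, seed=self.seed)
        hybrid = train_hybrid(
            self.images,
            cnn_config=self.cnn_config,
            rf_config=self.rf_config,
            folds=folds,
            preprocess=self.preprocess,
            augment=self.augment,
        )
        return SegmenterResults(model=self, hybrid=hybrid, folds=folds)


@dataclass
class SegmenterResults:
    """Fitted hybrid with diagnostics and downstream analyses."""

    model: SporeLayerSegmenter
    hybrid: HybridModel
    folds: FoldSplit
    _last_report: MetricsReport | None = field(default=None, repr=False)

    @property
    def fold_reports(self) -> list[dict]:
        return self.hybrid.fold_reports

    def predict(self, image: AnnotatedImage) -> SegmentationMap:
        return self.hybrid.segment(image)

    def evaluate(self, test: list[AnnotatedImage]) -> tuple[MetricsReport, np.ndarray]:
        report, acc = evaluate_hybrid(self.hybrid, test)
        self._last_report = report
        return report, acc

    def quantify(self, image: AnnotatedImage, image_id: str = "") -> LayerRatios:
        return layer_ratios(self.predict(image), image_id=image_id)

    def summary(self) -> str:
        lines = []
        cfg = self.model.cnn_config
        lines.append("Spore layer segmenter (hybrid CNN + random forest)")
        lines.append("=" * 52)
        lines.append(
            f"Encoder: {cfg.conv_layer_count} conv / {cfg.pool_layer_count} pool layers, "
            f"{cfg.feature_channels} feature channels, stride {cfg.total_stride}"
        )
        lines.append(
            f"Forest : {self.hybrid.rf.n_trees} trees, "
            f"{self.hybrid.rf.config.features_per_split} candidate features/split"
        )
        lines.append(f"Folds  : k={self.folds.k}, seed={self.folds.seed}")
        for rep in self.fold_reports:
            lines.append(
                f"  fold {rep['fold']}: {len(rep['train_ids'])} train / "
                f"{len(rep['val_ids'])} val ids ({rep['n_train_items']} items), "
                f"best val loss {rep['best_val_loss']:.4f} "
                f"@ epoch {rep['history'].checkpoint_epoch}"
            )
        if self._last_report is not None:
            rep = self._last_report
            lines.append("Last evaluation")
            lines.append(f"  overall accuracy : {rep.overall_accuracy:.3f}")
            lines.append(f"  macro precision  : {rep.macro_precision:.3f}")
            lines.append(f"  macro sensitivity: {rep.macro_sensitivity:.3f}")
            lines.append(f"  macro F1         : {rep.macro_f1:.3f}")
            lines.append(f"  support          : {rep.total_support}")
        return "\n".join(lines)

    def plot_segmentation(self, image: AnnotatedImage, ax=None):
        """Render the predicted label grid with the 8-class palette."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        segmap = self.predict(image)
        if ax is None:
            _, ax = plt.subplots()
        cmap = ListedColormap([c.display_color for c in DEFAULT_SCHEME.classes])
        ax.imshow(segmap.labels, cmap=cmap, vmin=1, vmax=8, interpolation="nearest")
        ax.set_title("predicted spore layers")
        ax.set_xticks([])
        ax.set_yticks([])
        return ax
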