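"""End-to-end orchestration of the hybrid CNN + random-forest training protocol.

Training uses three-fold cross-validation over the training pool only: per
fold, the encoder is trained on two-thirds of the pool with the remaining
third as validation (checkpointing on best validation loss), the fold with
the lowest best validation loss supplies the final encoder, features are
then extracted from the full training pool and the random forest is fitted
on them.  Held-out evaluation and the two reference baselines (random
forest on raw 16x16 block-mean intensities; constant majority-class
prediction) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cnn_features import (
    CNNConfig,
    FeatureExtractor,
    TrainingHistory,
    build_feature_extractor,
    extract_features,
    train_feature_extractor,
)
from .errors import ConfigurationError
from .evaluate import MetricsReport, confusion_matrix, metrics_report, per_image_accuracy
from .forest import (
    PixelForest,
    RFConfig,
    build_pixel_dataset,
    fit_random_forest,
    rf_predict,
    segment_image,
)
from .image import AnnotatedImage
from .labels import DEFAULT_SCHEME, LabelScheme
from .preprocess import (
    DOWNSAMPLE_FACTOR,
    PreprocessConfig,
    augment_pair,
    downsample_mask,
    normalize,
    resize_pair,
)

__all__ = [
    "FoldSplit",
    "HybridModel",
    "make_folds",
    "train_hybrid",
    "evaluate_hybrid",
    "baseline_rf_raw",
    "baseline_majority",
]


@dataclass(frozen=True)
class FoldSplit:
    """k disjoint validation partitions whose union is the full id set."""

    k: int
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, val) per fold
    seed: int

    def __post_init__(self) -> None:
        all_val: list[int] = []
        ids = set()
        for train, val in self.folds:
            if set(train) & set(val):
                raise ConfigurationError("train and validation ids overlap")
            all_val.extend(val)
            ids.update(train)
            ids.update(val)
        if len(all_val) != len(set(all_val)):
            raise ConfigurationError("validation sets are not disjoint")
        if set(all_val) != ids:
            raise ConfigurationError("validation sets must cover the full id set")
        for train, val in self.folds:
            if set(train) != ids - set(val):
                raise ConfigurationError("train set must complement its validation set")


def make_folds(ids: list, k: int = 3, seed: int = 0) -> FoldSplit:
    """Seeded shuffle, then k near-equal validation partitions.

    Remainder items go to the earliest folds, so 10 ids at k=3 give
    validation sizes 4, 3, 3.
    """
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least k={k} ids, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        val = tuple(int(j) for j in order[start : start + size])
        train = tuple(int(j) for j in order if int(j) not in val)
        folds.append((train, val))
        start += size
    return FoldSplit(k=k, folds=tuple(folds), seed=seed)


@dataclass
class HybridModel:
    """The trained encoder + forest pair with its full provenance."""

    cnn: FeatureExtractor
    rf: PixelForest
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(target_size=None))
    fold_reports: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rf.n_features != self.cnn.config.feature_channels:
            raise ConfigurationError(
                "forest feature width must equal the encoder's channel count"
            )

    def segment(self, image: AnnotatedImage):
        return segment_image(self.cnn, self.rf, self._prepare(image))

    def _prepare(self, image: AnnotatedImage) -> AnnotatedImage:
        return normalize(resize_pair(image, self.preprocess))


def _prepare_pool(
    images: list[AnnotatedImage], pre: PreprocessConfig
) -> list[AnnotatedImage]:
    return [normalize(resize_pair(img, pre)) for img in images]


def train_hybrid(
    images: list[AnnotatedImage],
    cnn_config: CNNConfig | None = None,
    rf_config: RFConfig | None = None,
    folds: FoldSplit | None = None,
    preprocess: PreprocessConfig | None = None,
    augment: bool = True,
) -> HybridModel:
    """Run the full training protocol on a mask-bearing training pool."""
    cnn_config = cnn_config or CNNConfig()
    rf_config = rf_config or RFConfig()
    preprocess = preprocess or PreprocessConfig(target_size=None)
    if any(img.mask is None for img in images):
        raise ValueError("every training image needs a mask")
    pool = _prepare_pool(images, preprocess)
    all_labels = np.unique(np.concatenate([img.mask.ravel() for img in pool]))
    if (all_labels[all_labels > 0]).size < 2:
        raise ValueError("training pool must contain at least 2 annotated classes")
    folds = folds or make_folds(list(range(len(pool))), k=3, seed=cnn_config.seed)

    fold_reports: list[dict] = []
    best: tuple[float, FeatureExtractor] | None = None
    for fold_idx, (train_ids, val_ids) in enumerate(folds.folds):
        train_items = [pool[i] for i in train_ids]
        if augment:
            train_items = train_items + [
                aug for img in train_items for aug in augment_pair(img)
            ]
        val_items = [pool[i] for i in val_ids]
        model = build_feature_extractor(replace(cnn_config, seed=cnn_config.seed + fold_idx))
        model, history = train_feature_extractor(model, train_items, val_items, model.config)
        best_val = float(min(history.val_loss))
        fold_reports.append(
            {
                "fold": fold_idx,
                "train_ids": list(train_ids),
                "val_ids": list(val_ids),
                "n_train_items": len(train_items),
                "history": history,
                "best_val_loss": best_val,
            }
        )
        if best is None or best_val < best[0]:
            best = (best_val, model)

    assert best is not None
    cnn = best[1]
    stacks = [extract_features(cnn, img) for img in pool]
    masks = [downsample_mask(img.mask, DOWNSAMPLE_FACTOR) for img in pool]
    data = build_pixel_dataset(stacks, masks, rf_config)
    rf = fit_random_forest(data, rf_config)
    return HybridModel(
        cnn=cnn,
        rf=rf,
        preprocess=preprocess,
        fold_reports=fold_reports,
        seed=cnn_config.seed,
    )


def evaluate_hybrid(
    model: HybridModel, test: list[AnnotatedImage]
) -> tuple[MetricsReport, np.ndarray]:
    """Segment each test image and score it against its downsampled mask."""
    if not test:
        raise ValueError("test set is empty")
    if any(img.mask is None for img in test):
        raise ValueError("every test image needs a mask")
    preds, masks = [], []
    for img in test:
        prepared = model._prepare(img)
        segmap = segment_image(model.cnn, model.rf, prepared)
        masks.append(downsample_mask(prepared.mask, DOWNSAMPLE_FACTOR))
        preds.append(segmap.labels)
    true_all = np.concatenate([m[m > 0] for m in masks])
    pred_all = np.concatenate([p[m > 0] for p, m in zip(preds, masks)])
    report = metrics_report(confusion_matrix(true_all, pred_all))
    return report, per_image_accuracy(preds, masks)


def _block_mean_features(image: AnnotatedImage, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Raw-pixel features: per-cell 16x16 block means, one per channel."""
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.ndim == 2:
        px = px[:, :, None]
    h, w, c = px.shape
    if h % factor or w % factor:
        raise ValueError(f"image dims {h}x{w} not divisible by {factor}")
    hb, wb = h // factor, w // factor
    means = px.reshape(hb, factor, wb, factor, c).mean(axis=(1, 3))
    return means.reshape(hb * wb, c).astype(np.float32)


def baseline_rf_raw(
    images: list[AnnotatedImage],
    test: list[AnnotatedImage],
    rf_config: RFConfig | None = None,
    preprocess: PreprocessConfig | None = None,
) -> float:
    """Held-out accuracy of a forest on raw block-mean intensities.

    The reference point for the hybrid: same forest protocol, but each grid
    cell is represented only by its mean gray level(s) instead of deep
    features.
    """
    rf_config = rf_config or RFConfig()
    preprocess = preprocess or PreprocessConfig(target_size=None)
    pool = _prepare_pool(images, preprocess)
    test_pool = _prepare_pool(test, preprocess)
    feats, labels = [], []
    rng = np.random.default_rng(rf_config.seed)
    for img in pool:
        f = _block_mean_features(img)
        m = downsample_mask(img.mask, DOWNSAMPLE_FACTOR).ravel()
        keep = m > 0
        f, m = f[keep], m[keep]
        cap = rf_config.max_pixels_per_image
        if cap is not None and f.shape[0] > cap:
            sel = rng.choice(f.shape[0], size=cap, replace=False)
            f, m = f[sel], m[sel]
        feats.append(f)
        labels.append(m)
    X = np.concatenate(feats)
    y = np.concatenate(labels)
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(
        n_estimators=rf_config.n_trees,
        criterion="gini",
        max_features=min(rf_config.features_per_split, X.shape[1]),
        bootstrap=rf_config.bootstrap,
        max_depth=rf_config.max_depth,
        random_state=rf_config.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    correct = 0
    total = 0
    for img in test_pool:
        f = _block_mean_features(img)
        m = downsample_mask(img.mask, DOWNSAMPLE_FACTOR).ravel()
        keep = m > 0
        if not keep.any():
            raise ValueError("test image has no scored cells")
        pred = clf.predict(f[keep])
        correct += int((pred == m[keep]).sum())
        total += int(keep.sum())
    return correct / total


def baseline_majority(images: list[AnnotatedImage], test: list[AnnotatedImage]) -> float:
    """Held-out accuracy of always predicting the most common training class."""
    train_labels = np.concatenate(
        [downsample_mask(img.mask, DOWNSAMPLE_FACTOR).ravel() for img in images]
    )
    train_labels = train_labels[train_labels > 0]
    majority = int(np.bincount(train_labels).argmax())
    correct = 0
    total = 0
    for img in test:
        m = downsample_mask(img.mask, DOWNSAMPLE_FACTOR).ravel()
        m = m[m > 0]
        correct += int((m == majority).sum())
        total += int(m.size)
    return correct / total
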