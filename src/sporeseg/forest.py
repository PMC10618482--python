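"""Pixel-level random-forest classification over CNN features.

Each 1/16-grid cell is one sample with a 1024-dimensional deep feature
vector.  Trees are grown on bootstrap resamples with the Gini impurity
criterion (1 − Σ pᵢ², zero at purity, where growth stops), considering 25
candidate features per split; the forest's hard majority vote — with ties
broken toward the lowest class index — assigns each cell one of the 8
layer classes.  Tree fitting is delegated to scikit-learn; vote counting
and the tie rule are implemented here, per tree, rather than through
scikit-learn's probability-averaged prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cnn_features import FeatureExtractor, FeatureStack, extract_features
from .image import AnnotatedImage
from .labels import N_CLASSES

__all__ = [
    "RFConfig",
    "PixelDataset",
    "SegmentationMap",
    "PixelForest",
    "gini_impurity",
    "majority_vote",
    "build_pixel_dataset",
    "fit_random_forest",
    "rf_predict",
    "segment_image",
]


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Labels (1..8) from per-class vote counts; ties go to the lowest index."""
    votes = np.asarray(votes)
    if votes.ndim != 2 or votes.shape[1] != N_CLASSES:
        raise ValueError(f"votes must be (N, {N_CLASSES}), got {votes.shape}")
    return (votes.argmax(axis=1) + 1).astype(np.uint8)


def gini_impurity(p) -> float:
    """Gini impurity 1 − Σ pᵢ² of a class-probability vector.

    Ranges over [0, 1 − 1/n]; zero iff one class holds all probability.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probability vector must be 1-D and nonempty")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 300
    features_per_split: int = 25
    bootstrap: bool = True
    class_weights: dict[int, float] | None = None
    max_pixels_per_image: int | None = 2000
    max_depth: int | None = None  # None = grow to purity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.features_per_split < 1:
            raise ValueError("features_per_split must be >= 1")


@dataclass
class PixelDataset:
    """Flattened grid cells: features (N, C), labels (N,) in 1..8, provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature rows and labels must align")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > N_CLASSES):
            raise ValueError("labels must lie in 1..8 (0 must be filtered out upstream)")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def build_pixel_dataset(
    stacks: list[FeatureStack],
    masks: list[np.ndarray],
    config: RFConfig,
) -> PixelDataset:
    """One row per labeled grid cell, subsampled per image at the configured cap."""
    if len(stacks) != len(masks):
        raise ValueError("need one mask per feature stack")
    rng = np.random.default_rng(config.seed)
    feats, labels, prov = [], [], []
    for stack, mask in zip(stacks, masks):
        mask = np.asarray(mask)
        if stack.values.shape[:2] != mask.shape:
            raise ValueError(
                f"stack grid {stack.values.shape[:2]} != mask grid {mask.shape}"
            )
        rows, cols = np.nonzero(mask > 0)
        if rows.size == 0:
            continue
        if config.max_pixels_per_image is not None and rows.size > config.max_pixels_per_image:
            keep = rng.choice(rows.size, size=config.max_pixels_per_image, replace=False)
            keep.sort()
            rows, cols = rows[keep], cols[keep]
        feats.append(stack.values[rows, cols])
        labels.append(mask[rows, cols].astype(np.int64))
        prov.extend((stack.image_id, int(r), int(c)) for r, c in zip(rows, cols))
    if not feats:
        return PixelDataset(
            features=np.empty((0, stacks[0].n_channels if stacks else 0), dtype=np.float32),
            labels=np.empty(0, dtype=np.int64),
        )
    return PixelDataset(
        features=np.concatenate(feats), labels=np.concatenate(labels), provenance=prov
    )


@dataclass
class PixelForest:
    """A fitted forest plus the metadata needed for vote bookkeeping."""

    sklearn_model: RandomForestClassifier
    config: RFConfig
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.sklearn_model.estimators_)


def fit_random_forest(data: PixelDataset, config: RFConfig | None = None) -> PixelForest:
    """Grow ``n_trees`` Gini trees on bootstrap resamples of the pixel data.

    Trees are expanded until nodes are pure (no depth cap by default), with
    ``features_per_split`` candidate features evaluated at each split.
    """
    config = config or RFConfig()
    if len(data) == 0:
        raise ValueError("cannot fit a forest on an empty pixel dataset")
    if np.unique(data.labels).size < 2:
        raise ValueError("pixel dataset must contain at least 2 distinct labels")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=min(config.features_per_split, data.features.shape[1]),
        bootstrap=config.bootstrap,
        class_weight=config.class_weights,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(data.features, data.labels)
    return PixelForest(sklearn_model=clf, config=config, n_features=data.features.shape[1])


def rf_predict(model: PixelForest, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard majority vote over the trees.

    Returns ``(labels, votes)`` where ``votes[i, c-1]`` counts trees voting
    class ``c`` for row ``i`` (rows sum to the tree count) and ``labels`` is
    the argmax with ties broken toward the lowest class index.
    """
    features = np.asarray(features, dtype=np.float32)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise ValueError(
            f"feature matrix must be (N, {model.n_features}), got {features.shape}"
        )
    clf = model.sklearn_model
    classes = clf.classes_.astype(int)
    votes = np.zeros((features.shape[0], N_CLASSES), dtype=np.int32)
    for est in clf.estimators_:
        pred = est.predict(features).astype(int)  # indices into classes_
        pred_labels = classes[pred]
        for c in classes:
            votes[:, c - 1] += pred_labels == c
    return majority_vote(votes), votes


@dataclass
class SegmentationMap:
    """Low-resolution label matrix (values 1..8) with per-cell vote counts."""

    labels: np.ndarray
    votes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.votes = np.asarray(self.votes)
        if self.labels.ndim != 2 or self.votes.shape != self.labels.shape + (N_CLASSES,):
            raise ValueError("votes must be labels shape + (8,)")
        if self.labels.min() < 1 or self.labels.max() > N_CLASSES:
            raise ValueError("segmentation labels must lie in 1..8")
        recomputed = self.votes.argmax(axis=2) + 1
        if not np.array_equal(recomputed, self.labels.astype(int)):
            raise ValueError("labels must equal the vote argmax (lowest-index ties)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=N_CLASSES + 1)[1:]


def segment_image(
    cnn_model: FeatureExtractor, rf_model: PixelForest, image: AnnotatedImage
) -> SegmentationMap:
    """Pixel-wise classification of one image at the 1/16 feature grid."""
    if rf_model.n_features != cnn_model.config.feature_channels:
        raise ValueError(
            f"forest expects {rf_model.n_features} features but the extractor "
            f"produces {cnn_model.config.feature_channels}"
        )
    stack = extract_features(cnn_model, image)
    hb, wb, _ = stack.values.shape
    labels, votes = rf_predict(rf_model, stack.as_matrix())
    return SegmentationMap(
        labels=labels.reshape(hb, wb), votes=votes.reshape(hb, wb, N_CLASSES)
    )
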