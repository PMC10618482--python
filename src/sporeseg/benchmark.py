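"""Desk-scale evaluation harness: phantom benchmark and damage study.

The benchmark trains the full-width hybrid (15-conv/5-pool encoder, 1024
feature channels) on 20 phantoms and scores 10 held-out phantoms, then
compares against the raw-pixel random forest and the constant
majority-class predictor.  Phantoms are 160x128 — the same 16-divisible
aspect family as full-size micrographs — and the encoder trains for 2
epochs without augmentation with a 100-tree / 300-cells-per-image forest,
sizes chosen so a replicate runs in minutes on one CPU while preserving
the protocol (3-fold checkpointing, feature extraction, forest fit).

The damage study trains only on intact phantoms, then segments matched
pairs of intact and fully core-damaged phantoms and compares the mean
predicted core ratio — the synthetic analog of reading chemical core
damage off an enlarged predicted core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn_features import CNNConfig
from .forest import RFConfig
from .phantom import PhantomConfig, apply_core_damage, generate_dataset
from .pipeline import (
    HybridModel,
    baseline_majority,
    baseline_rf_raw,
    evaluate_hybrid,
    train_hybrid,
)
from .quantify import layer_ratios

__all__ = [
    "DESK_IMAGE_SIZE",
    "DESK_N_TRAIN",
    "DESK_N_TEST",
    "desk_phantom_config",
    "desk_cnn_config",
    "desk_rf_config",
    "BenchmarkReplicate",
    "run_benchmark_replicate",
    "DamageStudy",
    "run_damage_study",
]

DESK_IMAGE_SIZE = (160, 128)
DESK_N_TRAIN = 20
DESK_N_TEST = 10
DESK_EPOCHS = 2
DESK_RF_TREES = 100
DESK_RF_CAP = 300


def desk_phantom_config() -> PhantomConfig:
    return PhantomConfig(image_size=DESK_IMAGE_SIZE)


def desk_cnn_config(seed: int) -> CNNConfig:
    return CNNConfig(epochs=DESK_EPOCHS, seed=seed)


def desk_rf_config(seed: int) -> RFConfig:
    return RFConfig(n_trees=DESK_RF_TREES, max_pixels_per_image=DESK_RF_CAP, seed=seed)


@dataclass
class BenchmarkReplicate:
    seed: int
    hybrid_accuracy: float
    train_accuracy: float
    raw_baseline_accuracy: float
    majority_baseline_accuracy: float
    cnn_head_accuracy: float
    per_image_accuracy: np.ndarray
    model: HybridModel = field(repr=False)
    n_scored_cells: int = 0


def _cnn_head_accuracy(model: HybridModel, test) -> float:
    from .preprocess import DOWNSAMPLE_FACTOR, downsample_mask

    correct = total = 0
    for img in test:
        prepared = model._prepare(img)
        pred = model.cnn.head_predict(prepared)
        mask = downsample_mask(prepared.mask, DOWNSAMPLE_FACTOR)
        scored = mask > 0
        correct += int((pred[scored] == mask[scored]).sum())
        total += int(scored.sum())
    return correct / total


def run_benchmark_replicate(seed: int) -> BenchmarkReplicate:
    """One seeded end-to-end run: train hybrid, score it and both baselines."""
    rng = np.random.default_rng(seed)
    train_seed, test_seed = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
    config = desk_phantom_config()
    train = generate_dataset(DESK_N_TRAIN, config, train_seed)
    test = generate_dataset(DESK_N_TEST, config, test_seed)
    rf_config = desk_rf_config(seed)
    model = train_hybrid(
        train, cnn_config=desk_cnn_config(seed), rf_config=rf_config, augment=False
    )
    report, per_image = evaluate_hybrid(model, test)
    train_report, _ = evaluate_hybrid(model, train)
    return BenchmarkReplicate(
        seed=seed,
        hybrid_accuracy=report.overall_accuracy,
        train_accuracy=train_report.overall_accuracy,
        raw_baseline_accuracy=baseline_rf_raw(train, test, rf_config),
        majority_baseline_accuracy=baseline_majority(train, test),
        cnn_head_accuracy=_cnn_head_accuracy(model, test),
        per_image_accuracy=per_image,
        model=model,
        n_scored_cells=report.total_support,
    )


@dataclass
class DamageStudy:
    control_core_ratios: np.ndarray
    damaged_core_ratios: np.ndarray
    control_cortex_ratios: np.ndarray
    damaged_cortex_ratios: np.ndarray
    n_pairs: int

    @property
    def control_core_mean(self) -> float:
        return float(self.control_core_ratios.mean())

    @property
    def damaged_core_mean(self) -> float:
        return float(self.damaged_core_ratios.mean())


def run_damage_study(model: HybridModel, n_pairs: int = 20, seed: int = 0) -> DamageStudy:
    """Segment matched intact/damaged phantom pairs with an intact-trained model."""
    rng = np.random.default_rng(seed)
    data_seed = int(rng.integers(0, 2**31 - 1))
    control = generate_dataset(n_pairs, desk_phantom_config(), data_seed)
    damaged = [
        apply_core_damage(img, 1.0, seed=int(rng.integers(0, 2**31 - 1)))
        for img in control
    ]
    ctrl = [layer_ratios(model.segment(img), image_id=f"ctrl_{i}") for i, img in enumerate(control)]
    dmg = [layer_ratios(model.segment(img), image_id=f"dmg_{i}") for i, img in enumerate(damaged)]
    return DamageStudy(
        control_core_ratios=np.array([r.core_ratio for r in ctrl]),
        damaged_core_ratios=np.array([r.core_ratio for r in dmg]),
        control_cortex_ratios=np.array([r.cortex_ratio for r in ctrl]),
        damaged_cortex_ratios=np.array([r.cortex_ratio for r in dmg]),
        n_pairs=n_pairs,
    )
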