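"""File formats, model persistence and run configuration.

Images travel as 8/16-bit grayscale or RGB PNG/TIFF; masks as
single-channel 8-bit PNG holding raw label values 0..8 (0 = unannotated),
never palette colors, so round-trips are lossless.  A trained hybrid is a
directory: encoder weights in an ``.npz``, the forest via joblib, and a
JSON manifest recording architecture, configurations and seeds so the two
halves can be integrity-checked against each other on load.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import joblib
import numpy as np
import tifffile
import yaml

from .cnn_features import CNNConfig, FeatureExtractor, build_feature_extractor
from .errors import ConfigurationError, IntegrityError
from .forest import PixelForest, RFConfig
from .image import AnnotatedImage
from .labels import N_CLASSES
from .phantom import PhantomConfig
from .pipeline import HybridModel
from .preprocess import PreprocessConfig

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_model",
    "load_model",
    "RunConfig",
]

_FORMAT_VERSION = 1


def read_image(path: str | Path) -> AnnotatedImage:
    """Read a PNG/TIFF micrograph; grayscale stays single-channel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] not in (1, 3, 4)):
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return AnnotatedImage(pixels=arr, meta={"source": str(path)})


def write_image(image: AnnotatedImage, path: str | Path) -> None:
    """Write pixels as PNG/TIFF.

    Integer arrays are written verbatim (lossless round-trip); float arrays
    in [0, 1] are scaled to 16-bit for TIFF and 8-bit for PNG.
    """
    path = Path(path)
    arr = np.asarray(image.pixels)
    suffix = path.suffix.lower()
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr, 0.0, 1.0)
        if suffix in (".tif", ".tiff"):
            arr = (arr * 65535).round().astype(np.uint16)
        else:
            arr = (arr * 255).round().astype(np.uint8)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask PNG; values must lie in {0..8}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel, got shape {arr.shape} in {path}")
    bad = np.unique(arr[arr > N_CLASSES])
    if bad.size:
        raise ValueError(f"mask {path} contains out-of-range label values {bad.tolist()}")
    if arr.max() == 0:
        warnings.warn(f"mask {path} is fully unannotated (all zeros)", stacklevel=2)
    return arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > N_CLASSES:
        raise ValueError("mask values must lie in {0..8}")
    iio.imwrite(Path(path), mask.astype(np.uint8))


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _cnn_config_from_dict(d: dict) -> CNNConfig:
    d = dict(d)
    for key in ("block_channels", "convs_per_block", "pool_strides"):
        if key in d:
            d[key] = tuple(d[key])
    return CNNConfig(**d)


def save_model(model: HybridModel, directory: str | Path) -> None:
    """Persist a hybrid as weights + forest + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = model.cnn.get_weights()
    np.savez(directory / "cnn_weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    joblib.dump(model.rf, directory / "rf.joblib")
    pre = dataclasses.asdict(model.preprocess)
    if pre["target_size"] is not None:
        pre["target_size"] = list(pre["target_size"])
    manifest = {
        "format_version": _FORMAT_VERSION,
        "architecture": model.cnn.manifest(),
        "cnn_config": _config_to_dict(model.cnn.config),
        "rf_config": _config_to_dict(model.rf.config),
        "preprocess": pre,
        "seed": model.seed,
        "n_weight_arrays": len(weights),
        "rf_n_features": model.rf.n_features,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> HybridModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"missing manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    for fname in ("cnn_weights.npz", "rf.joblib"):
        if not (directory / fname).exists():
            raise IntegrityError(f"model directory {directory} is missing {fname}")

    cnn_config = _cnn_config_from_dict(manifest["cnn_config"])
    if manifest["architecture"]["feature_channels"] != cnn_config.feature_channels:
        raise IntegrityError("manifest architecture disagrees with the encoder config")
    cnn = build_feature_extractor(cnn_config)
    with np.load(directory / "cnn_weights.npz") as npz:
        weights = [npz[f"w{i}"] for i in range(manifest["n_weight_arrays"])]
    cnn.set_weights(weights)

    rf: PixelForest = joblib.load(directory / "rf.joblib")
    if rf.n_features != manifest["rf_n_features"]:
        raise IntegrityError("forest feature width disagrees with the manifest")
    if rf.n_features != cnn_config.feature_channels:
        raise IntegrityError(
            f"forest expects {rf.n_features} features but the encoder "
            f"produces {cnn_config.feature_channels}"
        )

    pre = dict(manifest["preprocess"])
    if pre.get("target_size") is not None:
        pre["target_size"] = tuple(pre["target_size"])
    return HybridModel(
        cnn=cnn,
        rf=rf,
        preprocess=PreprocessConfig(**pre),
        seed=manifest.get("seed", 0),
    )


_SECTION_TYPES = {
    "phantom": PhantomConfig,
    "preprocess": PreprocessConfig,
    "cnn": CNNConfig,
    "rf": RFConfig,
    "pipeline": None,  # free-form: k, augment, n_train, n_test
    "quantify": None,  # free-form: denominator
}

_PIPELINE_KEYS = {"k", "augment", "n_train", "n_test"}
_QUANTIFY_KEYS = {"denominator"}


@dataclasses.dataclass
class RunConfig:
    """Nested run configuration with strict key checking and lossless round-trip."""

    seed: int = 0
    out_dir: str = "."
    sections: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.sections.items():
            if name not in _SECTION_TYPES:
                raise ConfigurationError(f"unknown config section {name!r}")
            cls = _SECTION_TYPES[name]
            if cls is not None:
                known = {f.name for f in dataclasses.fields(cls)}
            elif name == "pipeline":
                known = _PIPELINE_KEYS
            else:
                known = _QUANTIFY_KEYS
            unknown = set(values) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in section {name!r}: {sorted(unknown)}"
                )

    def section(self, name: str) -> dict[str, Any]:
        return dict(self.sections.get(name, {}))

    def to_dict(self) -> dict[str, Any]:
        return {"seed": self.seed, "out_dir": self.out_dir, **self.sections}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        seed = d.pop("seed", 0)
        out_dir = d.pop("out_dir", ".")
        return cls(seed=seed, out_dir=out_dir, sections=d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)
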