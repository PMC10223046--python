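"""End-to-end pipeline: simulate/read -> split -> preprocess -> train -> evaluate.

A :class:`PipelineConfig` fully describes a run; ``run_pipeline`` executes it
and writes a metrics CSV, the fitted transforms, a model checkpoint, the
per-epoch training log, and a JSON manifest (config + seed + versions) from
which the run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import swirclass
from swirclass.dl_models import CNNSpec, ConvLayerSpec, ModelSpec, build_model
from swirclass.nn.layers import Sequential
from swirclass.preprocess import (
    SplitSpec,
    apply_pca,
    apply_standardizer,
    fit_pca,
    fit_standardizer,
    save_transforms,
    systematic_split,
)
from swirclass.spectra_io import SpectraDataset, WavelengthGrid, read_dataset, subset_by_state
from swirclass.synthgen import BandSpec, GeneratorConfig, generate_dataset
from swirclass.train_eval import (
    PROCESSINGS,
    TrainConfig,
    evaluate_predictions,
    predict,
    train_classifier,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one classification run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_path: str | None = None
    state: str | None = None  # None = pool both physical states
    split: SplitSpec = field(default_factory=SplitSpec)
    processing: str = "pca"
    pca_k: int = 100
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "swirclass_run"

    def __post_init__(self) -> None:
        if self.processing not in PROCESSINGS:
            raise ValueError(f"processing must be one of {PROCESSINGS}, got {self.processing!r}")
        if self.processing == "pca" and self.pca_k < 1:
            raise ValueError("pca_k must be >= 1 when processing is 'pca'")


def _build_nested(cls, data: dict[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {unknown}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        if name == "bands" and isinstance(value, list):
            value = tuple(BandSpec(**b) for b in value)
        elif name == "conv_layers" and isinstance(value, list):
            value = tuple(ConvLayerSpec(**c) for c in value)
        elif name == "generator" and isinstance(value, dict):
            value = _build_nested(GeneratorConfig, value, f"{path}.generator")
        elif name == "grid" and isinstance(value, dict):
            value = _build_nested(WavelengthGrid, value, f"{path}.grid")
        elif name == "split" and isinstance(value, dict):
            value = _build_nested(SplitSpec, value, f"{path}.split")
        elif name == "model" and isinstance(value, dict):
            value = _build_nested(ModelSpec, value, f"{path}.model")
        elif name == "cnn" and isinstance(value, dict):
            value = _build_nested(CNNSpec, value, f"{path}.cnn")
        elif name == "train" and isinstance(value, dict):
            value = _build_nested(TrainConfig, value, f"{path}.train")
        elif name == "stratify_by" and isinstance(value, list):
            value = tuple(value)
        elif name == "continuum_coeffs" and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Parse a config mapping (e.g. loaded from YAML); unknown keys error."""
    return _build_nested(PipelineConfig, data, "pipeline")


def config_to_dict(cfg) -> Any:
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return [config_to_dict(v) for v in cfg]
    return cfg


def save_checkpoint(model: Sequential, path: str | Path) -> Path:
    path = Path(path)
    np.savez(path, **{f"param_{i:04d}": p for i, p in enumerate(model.parameters())})
    return path


def load_checkpoint(model: Sequential, path: str | Path) -> Sequential:
    data = np.load(Path(path))
    params = model.parameters()
    if len(data.files) != len(params):
        raise ValueError(
            f"checkpoint has {len(data.files)} arrays but model has {len(params)} parameters"
        )
    for i, p in enumerate(params):
        saved = data[f"param_{i:04d}"]
        if saved.shape != p.shape:
            raise ValueError(f"parameter {i} shape mismatch: {saved.shape} vs {p.shape}")
        p[...] = saved
    return model


def _load_or_generate(cfg: PipelineConfig) -> SpectraDataset:
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input dataset not found: {path}")
        return read_dataset(path, cfg.generator.grid)
    return generate_dataset(cfg.generator)


def run_pipeline(cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Execute the full flow and write artifacts to ``cfg.output_dir``.

    Returns the one-row metrics table (state, processing, model, accuracy,
    precision, recall, f1, seed).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = _load_or_generate(cfg)
    if cfg.state is not None:
        ds = subset_by_state(ds, cfg.state)
    train_ds, test_ds = systematic_split(ds, cfg.split)

    std = fit_standardizer(train_ds) if cfg.processing in ("standardization", "pca") else None
    pca = None
    if cfg.processing == "raw":
        Xtr, Xte = train_ds.X, test_ds.X
    else:
        train_s = apply_standardizer(train_ds, std)
        test_s = apply_standardizer(test_ds, std)
        if cfg.processing == "standardization":
            Xtr, Xte = train_s.X, test_s.X
        else:
            k = min(cfg.pca_k, len(train_s) - 1, train_s.grid.n_points)
            pca = fit_pca(train_s, k)
            Xtr, Xte = apply_pca(train_s, pca), apply_pca(test_s, pca)
    save_transforms(out / "transforms.npz", standardizer=std, pca=pca)

    model = build_model(cfg.model, Xtr.shape[1], seed=cfg.train.seed)
    log = train_classifier(model, Xtr, train_ds.labels, cfg.train)
    log.to_csv(out / "training_log.csv", index=False)
    save_checkpoint(model, out / "checkpoint.npz")

    y_pred = predict(model, Xte)
    rep = evaluate_predictions(test_ds.labels, y_pred)
    metrics = pd.DataFrame(
        [
            {
                "state": cfg.state if cfg.state is not None else "all",
                "processing": cfg.processing,
                "model": cfg.model.kind,
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
                "seed": cfg.train.seed,
                "n_train": len(train_ds),
                "n_test": len(test_ds),
            }
        ]
    )
    metrics.to_csv(out / "metrics.csv", index=False)

    manifest = {
        "config": config_to_dict(cfg),
        "seed": cfg.train.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "swirclass": swirclass.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return metrics
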