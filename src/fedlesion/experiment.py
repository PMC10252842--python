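"""Experiment configuration, manifests, and the end-to-end driver.

A single flat configuration describes the whole desk-scale experiment:
the synthetic dataset, the client partition, the CNN architecture, and
the federation/training hyperparameters.  Two profiles are built in —
``desk`` (50 rounds, 3 local epochs, batch 32, 16x16 images; runs in
minutes on one CPU) and ``paper`` (1000 rounds, 60 epochs, batch 128,
matching the published experimental settings; for users with real
compute).  Everything derives from one master seed, so a run is exactly
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .baselines import run_baseline
from .client import TrainConfig
from .data import (
    FederatedPartition,
    LabeledImageSet,
    default_class_specs,
    generate_lesion_dataset,
    partition_balanced,
    partition_dirichlet,
)
from .errors import ConfigurationError
from .model import ArchitectureSpec, default_architecture
from .server import FederationConfig, TrainingHistory, rounds_to_accuracy, run_async_fl

__all__ = [
    "ExperimentConfig",
    "PROFILES",
    "load_config",
    "save_config",
    "build_world",
    "run_experiment",
    "compare_algorithms",
    "RunManifest",
]

#: Profile presets.  ``paper`` carries the published settings (5 clients,
#: 1000 rounds, 60 epochs, batch 128, learning rate 0.001); ``desk``
#: scales rounds/epochs/batch down to desk hardware.
PROFILES: dict[str, dict] = {
    "desk": {"rounds": 50, "epochs": 3, "batch_size": 32, "image_size": 16},
    "paper": {"rounds": 1000, "epochs": 60, "batch_size": 128, "image_size": 16},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Flat, fully resolved experiment description."""

    # federation
    algorithm: str = "async"
    clients: int = 5
    fraction: float = 1.0
    rounds: int = 50
    es_period: int = 2
    alpha: float = float(np.e) / 2.0
    # local training
    epochs: int = 3
    batch_size: int = 32
    lr: float = 0.001
    optimizer: str = "sgd"
    activation: str = "relu"
    dropout_rate: float = 0.2
    # synthetic data
    n_classes: int = 4
    samples_per_class: int = 200
    eval_per_class: int = 50
    image_size: int = 16
    channels: int = 1
    noise_sd: float = 0.1
    partition: str = "balanced"
    concentration: float = 0.5
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.algorithm in ("async", "fedavg", "fedsgd"), "algorithm"),
            (self.clients >= 1, "clients"),
            (0.0 < self.fraction <= 1.0, "fraction"),
            (self.rounds >= 0, "rounds"),
            (self.es_period >= 1, "es_period"),
            (self.alpha > 1.0, "alpha"),
            (self.epochs >= 0, "epochs"),
            (self.batch_size >= 1, "batch_size"),
            (self.lr > 0, "lr"),
            (self.optimizer in ("sgd", "adam"), "optimizer"),
            (self.activation == "relu", "activation"),
            (0.0 <= self.dropout_rate < 1.0, "dropout_rate"),
            (self.n_classes >= 2, "n_classes"),
            (self.samples_per_class >= 1, "samples_per_class"),
            (self.eval_per_class >= 1, "eval_per_class"),
            (self.image_size >= 8, "image_size"),
            (self.channels >= 1, "channels"),
            (self.noise_sd >= 0, "noise_sd"),
            (self.partition in ("balanced", "dirichlet"), "partition"),
            (self.concentration > 0, "concentration"),
            (self.seed >= 0, "seed"),
        ]
        for ok, key in checks:
            if not ok:
                raise ConfigurationError(f"invalid value for config key '{key}'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


def load_config(path: str | None = None, profile: str = "desk", **overrides) -> ExperimentConfig:
    """Resolve a configuration from profile defaults, a YAML file, and overrides.

    The file is a flat key/value mapping; unknown keys are rejected and
    every value is validated, the error naming the offending key.  With
    no path the profile defaults are returned.
    """
    if profile not in PROFILES:
        raise ConfigurationError(f"unknown profile '{profile}'")
    values: dict = dict(PROFILES[profile])
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must be a flat key/value mapping")
        values.update(loaded)
    values.update(overrides)
    valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    try:
        return ExperimentConfig(**values)
    except TypeError as exc:  # wrong type for a key
        raise ConfigurationError(str(exc)) from exc


def save_config(cfg: ExperimentConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def build_world(
    cfg: ExperimentConfig, seed: int | None = None
) -> tuple[FederatedPartition, LabeledImageSet, ArchitectureSpec]:
    """Generate the synthetic dataset, client partition, and architecture."""
    master = cfg.seed if seed is None else seed
    specs = default_class_specs(cfg.n_classes, cfg.noise_sd)
    shape = (cfg.image_size, cfg.image_size, cfg.channels)
    train = generate_lesion_dataset(
        specs, [cfg.samples_per_class] * cfg.n_classes, shape, seed=derive_seed(master, "data", 0)
    )
    eval_set = generate_lesion_dataset(
        specs, [cfg.eval_per_class] * cfg.n_classes, shape, seed=derive_seed(master, "data", 1)
    )
    if cfg.partition == "balanced":
        part = partition_balanced(train, cfg.clients, seed=derive_seed(master, "data", 2))
    else:
        part = partition_dirichlet(
            train, cfg.clients, cfg.concentration, seed=derive_seed(master, "data", 2)
        )
    arch = default_architecture(cfg.n_classes, shape, dropout_rate=cfg.dropout_rate)
    return part, eval_set, arch


def run_experiment(
    cfg: ExperimentConfig, algorithm: str | None = None, seed: int | None = None
) -> TrainingHistory:
    """Generate the world and run one federated training experiment."""
    algorithm = algorithm or cfg.algorithm
    master = cfg.seed if seed is None else seed
    part, eval_set, arch = build_world(cfg, master)
    fed_cfg = FederationConfig(
        clients=cfg.clients,
        fraction=cfg.fraction,
        rounds=cfg.rounds,
        es_period=cfg.es_period,
        alpha=cfg.alpha,
        seed=master,
    )
    train_cfg = TrainConfig(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        optimizer=cfg.optimizer,
        dropout=cfg.dropout_rate > 0,
        seed=master,
    )
    if algorithm == "async":
        return run_async_fl(fed_cfg, train_cfg, part, eval_set, arch)
    return run_baseline(algorithm, fed_cfg, train_cfg, part, eval_set, arch)


def compare_algorithms(
    cfg: ExperimentConfig,
    seeds: Sequence[int],
    algorithms: Sequence[str] = ("fedsgd", "fedavg", "async"),
    target: float = 0.9,
) -> pd.DataFrame:
    """Mean +- sd of final accuracy, rounds-to-target, and uplink per algorithm.

    One row per algorithm, deterministic for a fixed seed list.  A seed
    that never reaches ``target`` contributes NaN to the
    rounds-to-target mean.
    """
    if not seeds:
        raise ConfigurationError("at least one seed is required")
    rows = []
    for algorithm in algorithms:
        finals, rtts, uplinks = [], [], []
        for seed in seeds:
            hist = run_experiment(cfg, algorithm=algorithm, seed=seed)
            finals.append(hist.records[-1].accuracy if hist.records else float("nan"))
            rtt = rounds_to_accuracy(hist, target)
            rtts.append(float("nan") if rtt is None else float(rtt))
            uplinks.append(hist.total_uplink())
        rows.append(
            {
                "algorithm": algorithm,
                "final_accuracy_mean": float(np.mean(finals)),
                "final_accuracy_sd": float(np.std(finals)),
                "rounds_to_target_mean": float(np.nanmean(rtts)) if not all(np.isnan(rtts)) else float("nan"),
                "seeds_reaching_target": int(np.sum(~np.isnan(rtts))),
                "total_uplink_scalars": int(np.mean(uplinks)),
            }
        )
    return pd.DataFrame(rows).set_index("algorithm")


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config: dict
    seed: int
    version: str = "fedlesion-0.1.0"
    input_fingerprints: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def fingerprint(arr: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_config(self) -> ExperimentConfig:
        return ExperimentConfig(**self.config)


def write_run_outputs(run_dir: str, cfg: ExperimentConfig, history: TrainingHistory) -> RunManifest:
    """Write history, metrics tables, checkpoint, and manifest to a directory."""
    from .client import evaluate_local  # noqa: F401  (kept close to usage below)
    from .metrics import communication_cost, confusion_matrix, macro_report
    from .model import forward, save_checkpoint

    os.makedirs(run_dir, exist_ok=True)
    os.makedirs(os.path.join(run_dir, "metrics"), exist_ok=True)
    history.save_csv(os.path.join(run_dir, "history.csv"))
    outputs = ["history.csv"]

    fingerprints = {}
    if history.final_params is not None:
        ckpt = os.path.join(run_dir, "checkpoint.npz")
        save_checkpoint(history.final_params, ckpt)
        outputs.append("checkpoint.npz")

        _, eval_set, _ = build_world(cfg)
        fingerprints["eval_images"] = RunManifest.fingerprint(eval_set.images)
        probs = forward(history.final_params, eval_set.images)
        cm = confusion_matrix(
            eval_set.labels, probs.argmax(axis=1), eval_set.n_classes, eval_set.class_names
        )
        report = macro_report(cm)
        report.per_class.mul(100.0).to_csv(os.path.join(run_dir, "metrics", "per_class.csv"))
        pd.DataFrame([report.to_summary_row(scale=100.0)]).to_csv(
            os.path.join(run_dir, "metrics", "summary.csv"), index=False
        )
        ledger = communication_cost(history)
        ledger.to_dataframe().to_csv(os.path.join(run_dir, "metrics", "ledger.csv"), index=False)
        bundle = {
            "summary": report.to_summary_row(scale=100.0),
            "per_class": report.per_class.to_dict(orient="index"),
            "confusion_matrix": cm.counts.tolist(),
            "total_uplink_scalars": ledger.total_uplink,
            "total_bytes": ledger.total_bytes,
        }
        with open(os.path.join(run_dir, "metrics", "report.json"), "w") as fh:
            json.dump(bundle, fh, indent=2)
        outputs += [
            "metrics/per_class.csv",
            "metrics/summary.csv",
            "metrics/ledger.csv",
            "metrics/report.json",
        ]

    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.seed, input_fingerprints=fingerprints, outputs=outputs
    )
    manifest.save(os.path.join(run_dir, "manifest.json"))
    return manifest
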