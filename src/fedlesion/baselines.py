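"""Synchronous reference algorithms: FedAvg and FedSGD.

Both exchange the full model every round.  FedAvg averages locally
trained models weighted by client sample counts; FedSGD averages a
single full-batch gradient per selected client and applies one server
step.  They share the client and model machinery and the seed
derivation of the asynchronous loop, so the asynchronous protocol with
ES = 1, C = 1 reproduces the FedAvg trajectory exactly (all caches
fresh, temporal weights all 1).
"""

from __future__ import annotations

import logging

import numpy as np

from ._rng import derive_seed
from .client import Client, ClientUpdate, TrainConfig, evaluate_local
from .data import FederatedPartition, LabeledImageSet
from .errors import ConfigurationError, StructuralError
from .model import ArchitectureSpec, Batch, LayeredParameters, build_model, loss_and_gradient
from .server import (
    FederationConfig,
    RoundRecord,
    TrainingHistory,
    select_clients,
)

__all__ = ["fedavg_aggregate", "fedsgd_round", "run_baseline"]

logger = logging.getLogger(__name__)


def fedavg_aggregate(updates: list[ClientUpdate]) -> LayeredParameters:
    """Sample-count-weighted mean of full-model updates (responders only)."""
    if not updates:
        raise ConfigurationError("cannot aggregate an empty update set")
    if any(u.flag != 1 or u.params is None for u in updates):
        raise StructuralError("FedAvg requires full-model updates")
    ref = updates[0].params
    total = sum(u.n_k for u in updates)
    if total <= 0:
        raise ConfigurationError("total sample count must be positive")
    arrays = {}
    for name in ref.arrays:  # type: ignore[union-attr]
        arrays[name] = sum(
            (u.n_k / total) * u.params.arrays[name] for u in updates  # type: ignore[union-attr]
        )
    return LayeredParameters(ref.arch, arrays)  # type: ignore[union-attr]


def fedsgd_round(
    global_params: LayeredParameters,
    partition: FederatedPartition,
    selected: tuple[int, ...],
    lr: float,
) -> LayeredParameters:
    """One FedSGD step: n_k-weighted mean of single full-batch gradients.

    Each selected client evaluates one exact gradient of its full local
    set at the current global model; the server applies one gradient
    step with rate ``lr``.  Dropout is off (the gradient is the
    deterministic full-batch one).
    """
    if lr <= 0:
        raise ConfigurationError("lr must be > 0")
    grads = []
    weights = []
    for k in selected:
        data = partition.client_sets[k]
        if len(data) == 0:
            logger.warning("fedsgd: client %d has no data, skipped", k)
            continue
        batch = Batch(data.images, data.labels)
        _, g = loss_and_gradient(global_params, batch, dropout_seed=None)
        grads.append(g)
        weights.append(len(data))
    if not grads:
        return global_params.copy()
    total = sum(weights)
    out = global_params.copy()
    for name in out.arrays:
        mean_grad = sum((w / total) * g[name] for w, g in zip(weights, grads))
        out.arrays[name] = out.arrays[name] - lr * mean_grad
    return out


def run_baseline(
    algorithm: str,
    fed_cfg: FederationConfig,
    train_cfg: TrainConfig,
    partition: FederatedPartition,
    eval_set: LabeledImageSet,
    arch: ArchitectureSpec,
    keep_snapshots: bool = False,
) -> TrainingHistory:
    """Synchronous run mirroring the asynchronous loop with flag = 1 always.

    ``algorithm`` is ``"fedavg"`` or ``"fedsgd"``.  Selection and
    client-training seeds follow the same derivation as the
    asynchronous loop so trajectories are comparable seed-for-seed.
    """
    if algorithm not in ("fedavg", "fedsgd"):
        raise ConfigurationError("algorithm must be 'fedavg' or 'fedsgd'")
    if fed_cfg.clients != partition.K:
        raise ConfigurationError(
            f"federation has {fed_cfg.clients} clients but partition has {partition.K}"
        )
    master = fed_cfg.seed
    global_model = build_model(arch, derive_seed(master, "init"))
    full_size = global_model.scalar_count()

    history = TrainingHistory(algorithm=algorithm)
    for t in range(1, fed_cfg.rounds + 1):
        selected = select_clients(
            fed_cfg.clients, fed_cfg.fraction, derive_seed(master, "select", t)
        )
        client_losses: list[float] = []
        responders: list[int] = []
        if algorithm == "fedavg":
            updates = []
            for k in selected:
                data = partition.client_sets[k]
                if len(data) == 0:
                    logger.warning("round %d: client %d has no data, skipped", t, k)
                    continue
                client = Client(k, data, retained=global_model.copy())
                upd = client.update(
                    global_model.copy(), 1, train_cfg, derive_seed(master, "client", t, k)
                )
                updates.append(upd)
                responders.append(k)
                client_losses.append(upd.final_loss)
            if updates:
                global_model = fedavg_aggregate(updates)
        else:
            responders = [k for k in selected if len(partition.client_sets[k]) > 0]
            global_model = fedsgd_round(global_model, partition, selected, train_cfg.lr)

        if keep_snapshots:
            history.snapshots.append(global_model.copy())
        loss, accuracy = evaluate_local(global_model, eval_set)
        traffic = len(responders) * full_size
        history.records.append(
            RoundRecord(
                round=t,
                flag=1,
                selected=selected,
                loss=loss,
                accuracy=accuracy,
                uplink_scalars=traffic,
                downlink_scalars=traffic,
                mean_client_loss=float(np.mean(client_losses)) if client_losses else float("nan"),
            )
        )
    history.final_params = global_model
    return history
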