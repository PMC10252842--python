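"""Center-server round loop with temporally weighted aggregation.

The server keeps, for every client k, the last full model and the last
shallow group it received, together with the rounds at which they
arrived (``timestamp_g`` and ``timestamp_s``).  Aggregation runs over
*all* K cached models — not just the round's responders — with each
client weighted by its data share n_k/n times a staleness decay
alpha^-(t - timestamp).  A fresh cache (timestamp = t) has weight
n_k/n, so with every client responding every round the rule reduces
exactly to federated averaging.

Rounds are numbered from 1.  Round t is a full-exchange round
(flag = 1, both layer groups travel) when t is a multiple of the
exchange period ES; otherwise only the shallow group travels and only
the global model's shallow group is replaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .client import Client, TrainConfig, evaluate_local
from .data import FederatedPartition, LabeledImageSet
from .errors import ConfigurationError, StateError, StructuralError
from .model import (
    ArchitectureSpec,
    DEEP,
    LayeredParameters,
    ParameterGroup,
    SHALLOW,
    build_model,
    split_layers,
)

__all__ = [
    "FederationConfig",
    "ClientRecord",
    "RoundRecord",
    "TrainingHistory",
    "select_clients",
    "exchange_flag",
    "temporal_weight",
    "temporally_weighted_aggregate",
    "run_async_fl",
    "rounds_to_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FederationConfig:
    """Federation-level knobs.

    ``clients`` is K, ``fraction`` the per-round participation fraction
    C (m = max(floor(C*K), 1) clients are drawn uniformly without
    replacement each round), ``rounds`` the total communication rounds
    T, ``es_period`` the full-exchange period ES, and ``alpha`` the
    staleness base (> 1; weight alpha^-staleness).
    """

    clients: int = 5
    fraction: float = 1.0
    rounds: int = 50
    es_period: int = 2
    alpha: float = float(np.e) / 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clients < 1:
            raise ConfigurationError("clients must be >= 1")
        if not (0.0 < self.fraction <= 1.0):
            raise ConfigurationError("fraction must be in (0, 1]")
        if self.rounds < 0:
            raise ConfigurationError("rounds must be >= 0")
        if self.es_period < 1:
            raise ConfigurationError("es_period must be >= 1")
        if self.alpha <= 1.0:
            raise ConfigurationError("alpha must be > 1")

    @property
    def m(self) -> int:
        return max(int(np.floor(self.fraction * self.clients)), 1)


@dataclass
class ClientRecord:
    """Server-side cache of one client's last-received parameters."""

    client_id: int
    n_k: int
    timestamp_g: int
    timestamp_s: int
    cached_full: LayeredParameters
    cached_shallow: ParameterGroup

    def check(self, t: int) -> None:
        if not (0 <= self.timestamp_g <= self.timestamp_s <= t):
            raise StateError(
                f"client {self.client_id}: timestamps "
                f"(g={self.timestamp_g}, s={self.timestamp_s}) out of order at round {t}"
            )


@dataclass
class RoundRecord:
    """One row of a run's history."""

    round: int
    flag: int
    selected: tuple[int, ...]
    loss: float
    accuracy: float
    uplink_scalars: int
    downlink_scalars: int
    mean_client_loss: float


@dataclass
class TrainingHistory:
    """Per-round log of a federated run plus the final global model."""

    records: list[RoundRecord] = field(default_factory=list)
    final_params: LayeredParameters | None = field(default=None, repr=False)
    algorithm: str = "async"
    #: per-round global models, populated only when a run is asked to
    #: keep snapshots (trajectory comparisons)
    snapshots: list[LayeredParameters] = field(default_factory=list, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "round": r.round,
                "flag": r.flag,
                "selected": " ".join(map(str, r.selected)),
                "loss": r.loss,
                "accuracy": r.accuracy,
                "uplink_scalars": r.uplink_scalars,
                "downlink_scalars": r.downlink_scalars,
                "mean_client_loss": r.mean_client_loss,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def save_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def total_uplink(self) -> int:
        return sum(r.uplink_scalars for r in self.records)


def select_clients(K: int, C: float, round_seed: int) -> tuple[int, ...]:
    """Uniform random selection of m = max(floor(C*K), 1) client ids."""
    if not (0.0 < C <= 1.0):
        raise ConfigurationError("fraction C must be in (0, 1]")
    m = max(int(np.floor(C * K)), 1)
    rng = np.random.default_rng(round_seed)
    return tuple(sorted(int(i) for i in rng.choice(K, size=m, replace=False)))


def exchange_flag(t: int, ES: int) -> int:
    """1 (full exchange) when round t is a multiple of ES, else 0."""
    if t < 1 or ES < 1:
        raise ConfigurationError("t and ES must be >= 1")
    return 1 if t % ES == 0 else 0


def temporal_weight(t: int, timestamp: int, alpha: float) -> float:
    """Staleness decay alpha^-(t - timestamp); 1 iff the cache is fresh."""
    if alpha <= 1.0:
        raise ConfigurationError("alpha must be > 1")
    if timestamp > t:
        raise StateError(f"timestamp {timestamp} lies after round {t}")
    return float(alpha ** -(t - timestamp))


def temporally_weighted_aggregate(
    records: list[ClientRecord], t: int, alpha: float, mode: str = "full"
) -> dict[str, np.ndarray]:
    """Normalized staleness-weighted combination of all cached models.

    Client k contributes raw weight (n_k / n) * alpha^-(t - timestamp)
    where timestamp and cache are the full-model ones in ``"full"``
    mode and the shallow ones in ``"shallow"`` mode; the output is the
    convex combination with weights normalized to sum to 1.
    """
    if mode not in ("full", "shallow"):
        raise ConfigurationError("mode must be 'full' or 'shallow'")
    if not records:
        raise ConfigurationError("no client records to aggregate")
    n = sum(r.n_k for r in records)
    if n <= 0:
        raise ConfigurationError("total sample count must be positive")

    raw = []
    array_sets = []
    for rec in records:
        rec.check(t)
        ts = rec.timestamp_g if mode == "full" else rec.timestamp_s
        arrays = rec.cached_full.arrays if mode == "full" else rec.cached_shallow.arrays
        raw.append((rec.n_k / n) * temporal_weight(t, ts, alpha))
        array_sets.append(arrays)

    names = list(array_sets[0])
    for arrays in array_sets[1:]:
        if list(arrays) != names or any(
            arrays[k].shape != array_sets[0][k].shape for k in names
        ):
            raise StructuralError("client caches are incongruent")

    total = float(np.sum(raw))
    weights = [w / total for w in raw]
    return {
        name: sum(w * arrays[name] for w, arrays in zip(weights, array_sets))
        for name in names
    }


def rounds_to_accuracy(history: TrainingHistory, target: float) -> int | None:
    """First round whose evaluation accuracy reaches ``target``, else None."""
    if not (0.0 <= target <= 1.0):
        raise ConfigurationError("target accuracy must be in [0, 1]")
    for rec in history.records:
        if rec.accuracy >= target:
            return rec.round
    return None


def run_async_fl(
    fed_cfg: FederationConfig,
    train_cfg: TrainConfig,
    partition: FederatedPartition,
    eval_set: LabeledImageSet,
    arch: ArchitectureSpec,
    keep_snapshots: bool = False,
) -> TrainingHistory:
    """Full asynchronous layer-partitioned federated run.

    Per round: compute the exchange flag and the selected set; broadcast
    the full global model (flag = 1) or only its shallow group
    (flag = 0); run local training at each selected client; refresh that
    client's server-side cache and timestamps (a shallow return
    refreshes only the shallow cache); aggregate over all K caches with
    temporal weights; evaluate the global model on ``eval_set``; log
    transmitted-scalar counts.  A failing client is skipped with a
    warning, never crashing the round.
    """
    if fed_cfg.clients != partition.K:
        raise ConfigurationError(
            f"federation has {fed_cfg.clients} clients but partition has {partition.K}"
        )
    master = fed_cfg.seed
    global_model = build_model(arch, derive_seed(master, "init"))
    full_size = global_model.scalar_count()
    shallow_size = global_model.shallow_count

    clients = [
        Client(k, partition.client_sets[k], retained=global_model.copy())
        for k in range(fed_cfg.clients)
    ]
    records = [
        ClientRecord(
            client_id=k,
            n_k=len(partition.client_sets[k]),
            timestamp_g=0,
            timestamp_s=0,
            cached_full=global_model.copy(),
            cached_shallow=split_layers(global_model)[0],
        )
        for k in range(fed_cfg.clients)
    ]

    history = TrainingHistory(algorithm="async")
    for t in range(1, fed_cfg.rounds + 1):
        flag = exchange_flag(t, fed_cfg.es_period)
        selected = select_clients(
            fed_cfg.clients, fed_cfg.fraction, derive_seed(master, "select", t)
        )
        payload = full_size if flag == 1 else shallow_size
        responders = []
        client_losses = []
        for k in selected:
            if len(clients[k].data) == 0:
                logger.warning("round %d: client %d has no data, skipped", t, k)
                continue
            incoming = (
                global_model.copy() if flag == 1 else split_layers(global_model)[0]
            )
            try:
                upd = clients[k].update(
                    incoming, flag, train_cfg, derive_seed(master, "client", t, k)
                )
            except Exception:  # a client failure must not kill the round
                logger.warning("round %d: client %d failed, skipped", t, k, exc_info=True)
                continue
            responders.append(k)
            client_losses.append(upd.final_loss)
            rec = records[k]
            if flag == 1:
                rec.cached_full = upd.params.copy()  # type: ignore[union-attr]
                rec.cached_shallow = split_layers(upd.params)[0]  # type: ignore[arg-type]
                rec.timestamp_g = t
                rec.timestamp_s = t
            else:
                rec.cached_shallow = upd.shallow.copy()  # type: ignore[union-attr]
                rec.timestamp_s = t

        if responders:
            if flag == 1:
                arrays = temporally_weighted_aggregate(records, t, fed_cfg.alpha, "full")
                global_model = LayeredParameters(arch, arrays)
            else:
                arrays = temporally_weighted_aggregate(records, t, fed_cfg.alpha, "shallow")
                global_model = global_model.overlay(ParameterGroup(arch, SHALLOW, arrays))

        if keep_snapshots:
            history.snapshots.append(global_model.copy())
        loss, accuracy = evaluate_local(global_model, eval_set)
        traffic = len(responders) * payload
        history.records.append(
            RoundRecord(
                round=t,
                flag=flag,
                selected=selected,
                loss=loss,
                accuracy=accuracy,
                uplink_scalars=traffic,
                downlink_scalars=traffic,
                mean_client_loss=float(np.mean(client_losses)) if client_losses else float("nan"),
            )
        )
        logger.info(
            "round %d flag=%d acc=%.4f loss=%.4f uplink=%d", t, flag, accuracy, loss, traffic
        )

    history.final_params = global_model
    return history
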