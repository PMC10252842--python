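"""Client-side local training and flag-dependent model return.

A client receives either the full global model (on a full-exchange
round, flag = 1) or only its shallow group (flag = 0, overlaid onto the
deep arrays the client retained from earlier rounds), trains the whole
model for E epochs of mini-batch gradient steps on its private
partition, and returns either the full model or only the shallow group
— the flag restricts the *return*, not the training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_seed
from .errors import ConfigurationError, InputError
from .data import LabeledImageSet
from .model import (
    Batch,
    LayeredParameters,
    ParameterGroup,
    SHALLOW,
    forward,
    loss_and_gradient,
    split_layers,
)

__all__ = ["TrainConfig", "ClientUpdate", "Client", "client_update", "evaluate_local", "sgd_train"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Local-training hyperparameters.

    ``optimizer`` is ``"sgd"`` (the plain gradient step of the client
    listing, default) or ``"adam"`` (adaptive-moment; fresh moment state
    per round).  ``dropout`` toggles the architecture's dropout rate
    during local training.
    """

    epochs: int = 3
    batch_size: int = 32
    lr: float = 0.001
    optimizer: str = "sgd"
    dropout: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ConfigurationError("optimizer must be 'sgd' or 'adam'")


@dataclass
class ClientUpdate:
    """What a client sends back to the server after local training."""

    client_id: int
    flag: int
    params: LayeredParameters | None  # full model when flag = 1
    shallow: ParameterGroup | None  # shallow group when flag = 0
    n_k: int
    final_loss: float

    def __post_init__(self) -> None:
        if self.flag == 1 and self.params is None:
            raise InputError("flag=1 update must carry the full model")
        if self.flag == 0:
            if self.shallow is None:
                raise InputError("flag=0 update must carry the shallow group")
            if self.shallow.tag != SHALLOW:
                raise InputError("flag=0 update must carry shallow-tagged arrays")

    def scalar_count(self) -> int:
        obj = self.params if self.flag == 1 else self.shallow
        return obj.scalar_count()  # type: ignore[union-attr]


def sgd_train(
    params: LayeredParameters,
    data: LabeledImageSet,
    cfg: TrainConfig,
    seed: int,
) -> tuple[LayeredParameters, float]:
    """E epochs of mini-batch steps; returns (trained params, last batch loss).

    Each epoch reshuffles the sample order with a seed derived from
    ``seed``; the final short batch is kept.  With ``epochs=0`` the
    parameters are returned unchanged and the loss is evaluated once.
    """
    if len(data) == 0:
        raise InputError("cannot train on an empty dataset")
    params = params.copy()
    if cfg.epochs == 0:
        loss, _ = evaluate_local(params, data)
        return params, loss

    adam_m: dict[str, np.ndarray] = {}
    adam_v: dict[str, np.ndarray] = {}
    adam_t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    loss = float("nan")
    step = 0
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(derive_seed(seed, "client", epoch))
        order = rng.permutation(len(data))
        for start in range(0, len(data), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = Batch(data.images[idx], data.labels[idx])
            dropout_seed = derive_seed(seed, "dropout", step) if cfg.dropout else None
            loss, grads = loss_and_gradient(params, batch, dropout_seed=dropout_seed)
            if cfg.optimizer == "sgd":
                for name in params.arrays:
                    params.arrays[name] -= cfg.lr * grads[name]
            else:
                adam_t += 1
                for name in params.arrays:
                    m = adam_m.setdefault(name, np.zeros_like(grads[name]))
                    v = adam_v.setdefault(name, np.zeros_like(grads[name]))
                    m += (1 - beta1) * (grads[name] - m)
                    v += (1 - beta2) * (grads[name] ** 2 - v)
                    m_hat = m / (1 - beta1**adam_t)
                    v_hat = v / (1 - beta2**adam_t)
                    params.arrays[name] -= cfg.lr * m_hat / (np.sqrt(v_hat) + eps)
            step += 1
    return params, float(loss)


def evaluate_local(
    params: LayeredParameters, dataset: LabeledImageSet, batch_size: int = 256
) -> tuple[float, float]:
    """Deterministic (dropout-off) mean cross-entropy and accuracy.

    Accuracy is the fraction of argmax predictions equal to the labels;
    numpy's argmax breaks probability ties toward the lowest class
    index.
    """
    if len(dataset) == 0:
        raise InputError("cannot evaluate on an empty dataset")
    losses = []
    correct = 0
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        probs = forward(params, dataset.images[sl])
        labels = dataset.labels[sl]
        p_true = probs[np.arange(len(labels)), labels]
        losses.append(-np.log(np.maximum(p_true, 1e-300)))
        correct += int(np.sum(probs.argmax(axis=1) == labels))
    loss = float(np.mean(np.concatenate(losses)))
    return loss, correct / len(dataset)


@dataclass
class Client:
    """A simulated hospital client: private data plus retained model state.

    The retained full model persists between rounds so that a
    shallow-only broadcast can be overlaid onto the client's own deep
    arrays before training.
    """

    client_id: int
    data: LabeledImageSet
    retained: LayeredParameters | None = field(default=None, repr=False)

    def update(
        self,
        incoming: LayeredParameters | ParameterGroup,
        flag: int,
        cfg: TrainConfig,
        seed: int,
    ) -> ClientUpdate:
        """Run one round of local training and build the return message."""
        if flag == 1:
            if not isinstance(incoming, LayeredParameters):
                raise InputError("flag=1 broadcast must be a full model")
            start = incoming.copy()
        else:
            if not isinstance(incoming, ParameterGroup) or incoming.tag != SHALLOW:
                raise InputError("flag=0 broadcast must be a shallow group")
            if self.retained is None:
                raise InputError("client has no retained model to overlay onto")
            start = self.retained.overlay(incoming)

        trained, final_loss = sgd_train(start, self.data, cfg, seed)
        self.retained = trained.copy()
        if flag == 1:
            return ClientUpdate(self.client_id, 1, trained, None, len(self.data), final_loss)
        shallow, _ = split_layers(trained)
        return ClientUpdate(self.client_id, 0, None, shallow, len(self.data), final_loss)


def client_update(
    k: int,
    incoming: LayeredParameters | ParameterGroup,
    flag: int,
    local_data: LabeledImageSet,
    cfg: TrainConfig,
    retained: LayeredParameters | None = None,
    seed: int | None = None,
) -> ClientUpdate:
    """Functional one-shot form of :meth:`Client.update`.

    ``retained`` supplies the client's previous full model, required
    when ``flag`` is 0.
    """
    client = Client(k, local_data, retained)
    return client.update(incoming, flag, cfg, cfg.seed if seed is None else seed)
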