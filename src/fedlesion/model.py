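"""A small convolutional classifier with layer-group (shallow/deep) tagging.

The federation protocol exchanges the model in two groups: the *shallow*
group (all convolutional stages, which learn generic image features and
travel every round) and the *deep* group (all fully connected stages,
which travel only on periodic full-exchange rounds).  Every parameter
array therefore carries exactly one of the two tags.

The network is implemented directly in numpy with exact analytic
gradients (float64 throughout), which keeps it verifiable against a
central finite-difference oracle at tight tolerance.  Layout per
convolution stage: convolution (valid padding) -> ReLU -> 2x2 pooling
(average by default); then fully connected stages with ReLU between
them, inverted dropout after the first hidden stage during training,
and a softmax over the class logits.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, InputError, StructuralError

__all__ = [
    "ConvStage",
    "ArchitectureSpec",
    "LayeredParameters",
    "ParameterGroup",
    "Batch",
    "default_architecture",
    "build_model",
    "forward",
    "loss_and_gradient",
    "split_layers",
    "merge_layers",
    "save_checkpoint",
    "load_checkpoint",
]

SHALLOW = "shallow"
DEEP = "deep"


@dataclass(frozen=True)
class ConvStage:
    """One convolution stage: ``filters`` kernels of size ``kernel``."""

    filters: int
    kernel: int = 3
    stride: int = 1

    def __post_init__(self) -> None:
        if self.filters < 1 or self.kernel < 1 or self.stride < 1:
            raise ConfigurationError("conv stage parameters must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Static description of the classifier.

    Parameters
    ----------
    input_shape:
        ``(H, W, C)`` of the images the network consumes.
    conv_stages:
        At least one :class:`ConvStage`; these arrays form the shallow
        group.
    fc_widths:
        Hidden fully connected widths (may be empty); the final
        classifier stage to ``n_classes`` is implicit.  FC arrays form
        the deep group.
    n_classes:
        Number of output classes L.
    pooling:
        ``"average"`` (default) or ``"max"``; 2x2, stride 2, applied
        after each conv stage whenever both spatial dims allow it.
    dropout_rate:
        Inverted-dropout rate in [0, 1), applied after the first hidden
        FC stage during training only.
    """

    input_shape: tuple[int, int, int]
    conv_stages: tuple[ConvStage, ...]
    fc_widths: tuple[int, ...]
    n_classes: int
    pooling: str = "average"
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_stages", tuple(self.conv_stages))
        object.__setattr__(self, "fc_widths", tuple(self.fc_widths))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        if len(self.conv_stages) < 1:
            raise ConfigurationError("at least one convolution stage is required")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.pooling not in ("average", "max"):
            raise ConfigurationError("pooling must be 'average' or 'max'")
        if any(w < 1 for w in self.fc_widths):
            raise ConfigurationError("fc widths must be >= 1")
        self.feature_shapes()  # raises on spatial collapse

    def feature_shapes(self) -> list[tuple[int, int, int]]:
        """Spatial shape after each conv stage (post pooling)."""
        H, W, C = self.input_shape
        if H < 1 or W < 1 or C < 1:
            raise ConfigurationError("input_shape must be positive")
        shapes = []
        for stage in self.conv_stages:
            H = (H - stage.kernel) // stage.stride + 1
            W = (W - stage.kernel) // stage.stride + 1
            if H < 1 or W < 1:
                raise ConfigurationError(
                    f"feature map collapses to {H}x{W} at stage {stage}"
                )
            if H >= 2 and W >= 2:
                H, W = H // 2, W // 2
            C = stage.filters
            shapes.append((H, W, C))
        return shapes

    def flat_features(self) -> int:
        H, W, C = self.feature_shapes()[-1]
        return H * W * C

    def parameter_shapes(self) -> dict[str, tuple[tuple[int, ...], str]]:
        """Ordered mapping name -> (shape, tag) for every parameter array."""
        shapes: dict[str, tuple[tuple[int, ...], str]] = {}
        C = self.input_shape[2]
        for i, stage in enumerate(self.conv_stages):
            shapes[f"conv{i}_w"] = ((stage.kernel, stage.kernel, C, stage.filters), SHALLOW)
            shapes[f"conv{i}_b"] = ((stage.filters,), SHALLOW)
            C = stage.filters
        fan_in = self.flat_features()
        for j, width in enumerate((*self.fc_widths, self.n_classes)):
            shapes[f"fc{j}_w"] = ((fan_in, width), DEEP)
            shapes[f"fc{j}_b"] = ((width,), DEEP)
            fan_in = width
        return shapes

    def parameter_count(self) -> int:
        return sum(int(np.prod(s)) for s, _ in self.parameter_shapes().values())

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "conv_stages": [[s.filters, s.kernel, s.stride] for s in self.conv_stages],
            "fc_widths": list(self.fc_widths),
            "n_classes": self.n_classes,
            "pooling": self.pooling,
            "dropout_rate": self.dropout_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArchitectureSpec":
        return cls(
            input_shape=tuple(d["input_shape"]),
            conv_stages=tuple(ConvStage(*s) for s in d["conv_stages"]),
            fc_widths=tuple(d["fc_widths"]),
            n_classes=int(d["n_classes"]),
            pooling=d.get("pooling", "average"),
            dropout_rate=float(d.get("dropout_rate", 0.2)),
        )


def default_architecture(
    n_classes: int, input_shape: tuple[int, int, int] = (16, 16, 1), dropout_rate: float = 0.2
) -> ArchitectureSpec:
    """Desk-scale default: two 3x3 conv stages (8, 16 filters), FC (32, L)."""
    return ArchitectureSpec(
        input_shape=input_shape,
        conv_stages=(ConvStage(8, 3, 1), ConvStage(16, 3, 1)),
        fc_widths=(32,),
        n_classes=n_classes,
        dropout_rate=dropout_rate,
    )


@dataclass
class ParameterGroup:
    """One tag group (shallow or deep) of a model's arrays."""

    arch: ArchitectureSpec
    tag: str
    arrays: dict[str, np.ndarray]

    def scalar_count(self) -> int:
        return sum(a.size for a in self.arrays.values())

    def copy(self) -> "ParameterGroup":
        return ParameterGroup(self.arch, self.tag, {k: v.copy() for k, v in self.arrays.items()})


@dataclass
class LayeredParameters:
    """Full model state: ordered named arrays, each tagged shallow or deep."""

    arch: ArchitectureSpec
    arrays: dict[str, np.ndarray]
    tags: dict[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tags:
            self.tags = {k: tag for k, (_, tag) in self.arch.parameter_shapes().items()}
        expected = self.arch.parameter_shapes()
        if set(self.arrays) != set(expected):
            raise StructuralError("parameter names do not match the architecture")
        for name, arr in self.arrays.items():
            if tuple(arr.shape) != expected[name][0]:
                raise StructuralError(
                    f"{name}: shape {arr.shape} != expected {expected[name][0]}"
                )

    def scalar_count(self) -> int:
        return sum(a.size for a in self.arrays.values())

    def group(self, tag: str) -> ParameterGroup:
        return ParameterGroup(
            self.arch, tag, {k: v.copy() for k, v in self.arrays.items() if self.tags[k] == tag}
        )

    @property
    def shallow_count(self) -> int:
        return sum(a.size for k, a in self.arrays.items() if self.tags[k] == SHALLOW)

    @property
    def deep_count(self) -> int:
        return sum(a.size for k, a in self.arrays.items() if self.tags[k] == DEEP)

    def copy(self) -> "LayeredParameters":
        return LayeredParameters(
            self.arch, {k: v.copy() for k, v in self.arrays.items()}, dict(self.tags)
        )

    def overlay(self, group: ParameterGroup) -> "LayeredParameters":
        """New model with ``group``'s arrays replacing the matching ones."""
        if group.arch != self.arch:
            raise StructuralError("group belongs to a different architecture")
        out = self.copy()
        for name, arr in group.arrays.items():
            if tuple(arr.shape) != out.arrays[name].shape:
                raise StructuralError(f"{name}: incongruent overlay shape")
            out.arrays[name] = arr.copy()
        return out

    def allclose(self, other: "LayeredParameters", atol: float = 0.0, rtol: float = 0.0) -> bool:
        return all(
            np.allclose(self.arrays[k], other.arrays[k], atol=atol, rtol=rtol)
            for k in self.arrays
        )


@dataclass
class Batch:
    """A mini-batch of images with integer labels."""

    images: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise InputError("batch images and labels must have equal length")
        if len(self.images) == 0:
            raise InputError("batch must be nonempty")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def build_model(arch: ArchitectureSpec, seed: int = 0) -> LayeredParameters:
    """Seeded He-style scaled-uniform initialization; biases zero.

    Weight arrays are drawn from U(-b, b) with b = sqrt(6 / fan_in);
    convolution arrays are tagged shallow, fully connected arrays deep.
    """
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for name, (shape, _tag) in arch.parameter_shapes().items():
        if name.endswith("_b"):
            arrays[name] = np.zeros(shape, dtype=np.float64)
        else:
            fan_in = int(np.prod(shape[:-1]))
            bound = np.sqrt(6.0 / fan_in)
            arrays[name] = rng.uniform(-bound, bound, size=shape)
    return LayeredParameters(arch, arrays)


# ---------------------------------------------------------------------------
# Forward / backward primitives
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    kh, kw, _, _ = w.shape
    N, H, W, _ = x.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    out = np.broadcast_to(b, (N, Ho, Wo, b.size)).copy()
    for di in range(kh):
        for dj in range(kw):
            xs = x[:, di : di + stride * Ho : stride, dj : dj + stride * Wo : stride, :]
            out += np.tensordot(xs, w[di, dj], axes=([3], [0]))
    return out


def _conv_backward(
    x: np.ndarray, w: np.ndarray, stride: int, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kh, kw, _, _ = w.shape
    _, Ho, Wo, _ = dout.shape
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for di in range(kh):
        for dj in range(kw):
            sl_i = slice(di, di + stride * Ho, stride)
            sl_j = slice(dj, dj + stride * Wo, stride)
            xs = x[:, sl_i, sl_j, :]
            dw[di, dj] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
            dx[:, sl_i, sl_j, :] += np.tensordot(dout, w[di, dj], axes=([3], [1]))
    db = dout.sum(axis=(0, 1, 2))
    return dx, dw, db


def _pool_forward(a: np.ndarray, kind: str) -> tuple[np.ndarray, tuple]:
    _, H, W, _ = a.shape
    if H < 2 or W < 2:
        return a, ("identity",)
    Ho, Wo = H // 2, W // 2
    crop = a[:, : 2 * Ho, : 2 * Wo, :]
    quads = np.stack(
        [crop[:, 0::2, 0::2], crop[:, 1::2, 0::2], crop[:, 0::2, 1::2], crop[:, 1::2, 1::2]]
    )
    if kind == "average":
        return quads.mean(axis=0), ("average", a.shape)
    arg = quads.argmax(axis=0)
    return np.take_along_axis(quads, arg[None], axis=0)[0], ("max", a.shape, arg)


def _pool_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    if cache[0] == "identity":
        return dout
    shape = cache[1]
    _, Ho, Wo, _ = dout.shape
    da = np.zeros(shape, dtype=dout.dtype)
    crop = da[:, : 2 * Ho, : 2 * Wo, :]
    slices = [crop[:, 0::2, 0::2], crop[:, 1::2, 0::2], crop[:, 0::2, 1::2], crop[:, 1::2, 1::2]]
    if cache[0] == "average":
        for sl in slices:
            sl += dout / 4.0
    else:
        arg = cache[2]
        for q, sl in enumerate(slices):
            sl += dout * (arg == q)
    return da


def _forward_pass(
    params: LayeredParameters,
    images: np.ndarray,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Returns (log_probs, probs, caches)."""
    arch = params.arch
    if tuple(images.shape[1:]) != arch.input_shape:
        raise InputError(
            f"images of shape {images.shape[1:]} do not match input {arch.input_shape}"
        )
    x = np.asarray(images, dtype=np.float64)
    caches: list = []
    for i, stage in enumerate(arch.conv_stages):
        w, b = params.arrays[f"conv{i}_w"], params.arrays[f"conv{i}_b"]
        z = _conv_forward(x, w, b, stage.stride)
        a = np.maximum(z, 0.0)
        p, pool_cache = _pool_forward(a, arch.pooling)
        caches.append(("conv", i, x, z, pool_cache))
        x = p
    flat_shape = x.shape
    a = x.reshape(len(x), -1)
    caches.append(("flatten", flat_shape))
    n_fc = len(arch.fc_widths) + 1
    for j in range(n_fc):
        w, b = params.arrays[f"fc{j}_w"], params.arrays[f"fc{j}_b"]
        z = a @ w + b
        if j < n_fc - 1:
            h = np.maximum(z, 0.0)
            mask = None
            if j == 0 and train and arch.dropout_rate > 0.0:
                if dropout_rng is None:
                    dropout_rng = np.random.default_rng(0)
                keep = 1.0 - arch.dropout_rate
                mask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * mask
            caches.append(("fc", j, a, z, mask))
            a = h
        else:
            caches.append(("fc_out", j, a))
            logits = z
    log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
    return log_probs, np.exp(log_probs), caches


def forward(params: LayeredParameters, batch: Batch | np.ndarray) -> np.ndarray:
    """Class probability vectors, one per sample; dropout disabled."""
    images = batch.images if isinstance(batch, Batch) else batch
    _, probs, _ = _forward_pass(params, images, train=False)
    return probs


def loss_and_gradient(
    params: LayeredParameters, batch: Batch, dropout_seed: int | None = None
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its exact gradient w.r.t. every array.

    ``dropout_seed`` seeds the (inverted) dropout mask; ``None`` runs
    without dropout regardless of the architecture's rate, which is
    what deterministic evaluation and gradient checking use.
    """
    train = dropout_seed is not None
    rng = np.random.default_rng(dropout_seed) if train else None
    log_probs, probs, caches = _forward_pass(params, batch.images, train=train, dropout_rng=rng)
    N = len(batch)
    if batch.labels.min() < 0 or batch.labels.max() >= params.arch.n_classes:
        raise InputError("labels out of range")
    loss = -float(np.mean(log_probs[np.arange(N), batch.labels]))

    grads = {name: np.zeros_like(arr) for name, arr in params.arrays.items()}
    dlogits = probs.copy()
    dlogits[np.arange(N), batch.labels] -= 1.0
    dlogits /= N

    da = dlogits
    arch = params.arch
    for cache in reversed(caches):
        kind = cache[0]
        if kind == "fc_out":
            _, j, a_in = cache
            grads[f"fc{j}_w"] = a_in.T @ da
            grads[f"fc{j}_b"] = da.sum(axis=0)
            da = da @ params.arrays[f"fc{j}_w"].T
        elif kind == "fc":
            _, j, a_in, z, mask = cache
            dh = da if mask is None else da * mask
            dz = dh * (z > 0.0)
            grads[f"fc{j}_w"] = a_in.T @ dz
            grads[f"fc{j}_b"] = dz.sum(axis=0)
            da = dz @ params.arrays[f"fc{j}_w"].T
        elif kind == "flatten":
            da = da.reshape(cache[1])
        else:  # conv stage
            _, i, x_in, z, pool_cache = cache
            da = _pool_backward(da, pool_cache)
            dz = da * (z > 0.0)
            stride = arch.conv_stages[i].stride
            dx, dw, db = _conv_backward(x_in, params.arrays[f"conv{i}_w"], stride, dz)
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
            da = dx
    return loss, grads


# ---------------------------------------------------------------------------
# Layer-group split / merge
# ---------------------------------------------------------------------------


def split_layers(params: LayeredParameters) -> tuple[ParameterGroup, ParameterGroup]:
    """Partition the model into its (shallow, deep) tag groups."""
    return params.group(SHALLOW), params.group(DEEP)


def merge_layers(shallow: ParameterGroup, deep: ParameterGroup) -> LayeredParameters:
    """Reassemble a model from its two tag groups (inverse of split)."""
    if shallow.arch != deep.arch:
        raise StructuralError("groups belong to different architectures")
    if shallow.tag != SHALLOW or deep.tag != DEEP:
        raise StructuralError("groups must carry the shallow and deep tags")
    arrays = {**{k: v.copy() for k, v in shallow.arrays.items()},
              **{k: v.copy() for k, v in deep.arrays.items()}}
    expected = shallow.arch.parameter_shapes()
    if set(arrays) != set(expected):
        raise StructuralError("groups do not jointly cover the architecture")
    return LayeredParameters(shallow.arch, arrays)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(params: LayeredParameters, path: str) -> None:
    """Named-array container with embedded architecture metadata."""
    meta = json.dumps({"arch": params.arch.to_dict(), "tags": params.tags})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **params.arrays)


def load_checkpoint(path: str) -> LayeredParameters:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arch = ArchitectureSpec.from_dict(meta["arch"])
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    return LayeredParameters(arch, arrays, dict(meta["tags"]))
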