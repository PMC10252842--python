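"""Synthetic lesion-like image generation and federated partitioning.

The simulator never downloads dermoscopy data.  Instead it generates
class-structured small images: each class is a fixed radial template (a
filled disk with a sinusoidal ring texture on a flat background) plus
per-image Gaussian pixel noise.  The template parameters differ per
class, so a small CNN can learn to separate the classes, while the noise
standard deviation controls task difficulty.

The module also carries the published bookkeeping tables of the
ISIC-2019 eight-class dermoscopy benchmark (per-class image counts and
their distribution over five hospital clients) as arithmetic fixtures,
so partition accounting can be checked against printed numbers without
the images themselves.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, InputError

__all__ = [
    "ClassSpec",
    "LabeledImageSet",
    "FederatedPartition",
    "ISIC_CLASSES",
    "isic2019_summary_table",
    "isic2019_client_table",
    "default_class_specs",
    "generate_lesion_dataset",
    "partition_balanced",
    "partition_dirichlet",
    "class_distribution_table",
    "save_dataset_png",
    "load_dataset_png",
    "save_dataset_npz",
    "load_dataset_npz",
    "save_partition_manifest",
]

# ---------------------------------------------------------------------------
# Published bookkeeping fixtures (ISIC-2019 eight-class benchmark)
# ---------------------------------------------------------------------------

#: Lesion class codes: melanoma, basal cell carcinoma, squamous cell
#: carcinoma, vascular lesion, melanocytic nevus, benign keratosis,
#: actinic keratosis, dermatofibroma.
ISIC_CLASSES = ("MLA", "BCC", "SCC", "VLN", "MCN", "BGK", "ATK", "DFA")

_ISIC_SUMMARY = {
    #        train  test  validation  total
    "MLA": (3812, 360, 350, 4522),
    "BCC": (2820, 250, 253, 3323),
    "SCC": (541, 42, 45, 628),
    "VLN": (202, 24, 27, 253),
    "MCN": (10979, 965, 931, 12875),
    "BGK": (2215, 203, 206, 2624),
    "ATK": (716, 75, 76, 867),
    "DFA": (206, 11, 22, 239),
}

_ISIC_CLIENT_ROWS = {
    # client -> per-class image counts, column order ISIC_CLASSES
    1: (904, 664, 126, 51, 2575, 524, 174, 49),
    2: (904, 665, 126, 50, 2575, 525, 174, 48),
    3: (904, 665, 125, 50, 2575, 524, 173, 47),
    4: (905, 665, 126, 51, 2575, 526, 173, 48),
    5: (905, 664, 125, 51, 2575, 525, 173, 47),
}


def isic2019_summary_table() -> pd.DataFrame:
    """Per-class train/test/validation/total image counts of ISIC-2019.

    Returns a DataFrame indexed by class code with columns
    ``train``, ``test``, ``validation``, ``total``.
    """
    return pd.DataFrame.from_dict(
        _ISIC_SUMMARY, orient="index", columns=["train", "test", "validation", "total"]
    ).rename_axis("class")


def isic2019_client_table() -> pd.DataFrame:
    """Published five-client distribution of the ISIC-2019 images.

    Rows are client ids 1..5, columns the eight class codes.
    """
    return pd.DataFrame.from_dict(
        _ISIC_CLIENT_ROWS, orient="index", columns=list(ISIC_CLASSES)
    ).rename_axis("client")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters of one synthetic lesion class.

    Parameters
    ----------
    mean_intensity:
        Intensity of the lesion interior, in [0, 1].
    blob_radius_frac:
        Lesion radius as a fraction of the half image side, > 0.
    texture_frequency:
        Number of sinusoidal rings across the lesion radius; 0 gives a
        flat disk.
    noise_sd:
        Standard deviation of per-pixel Gaussian noise, >= 0.  With 0
        every image of the class is the identical template.
    """

    mean_intensity: float
    blob_radius_frac: float
    texture_frequency: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.blob_radius_frac <= 0:
            raise ConfigurationError("blob_radius_frac must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.texture_frequency < 0:
            raise ConfigurationError("texture_frequency must be >= 0")


@dataclass
class LabeledImageSet:
    """Images with integer class labels.

    ``images`` is an ``(N, H, W, C)`` float array of intensities in
    [0, 1]; ``labels`` holds class indices into ``class_names``.
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.class_names = tuple(self.class_names)
        if self.images.ndim != 4:
            raise InputError("images must be an (N, H, W, C) array")
        if len(self.images) != len(self.labels):
            raise InputError("images and labels must have equal length")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise InputError("labels must be valid class indices")
        if len(self.images) and (self.images.min() < 0 or self.images.max() > 1):
            raise InputError("image intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]

    def class_counts(self) -> np.ndarray:
        """Per-class sample counts, length ``n_classes``."""
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: np.ndarray | Sequence[int]) -> "LabeledImageSet":
        idx = np.asarray(indices, dtype=np.int64)
        return LabeledImageSet(self.images[idx], self.labels[idx], self.class_names)


@dataclass
class FederatedPartition:
    """Disjoint assignment of a dataset's samples to K clients.

    ``client_indices[k]`` indexes into the source dataset; together the
    index arrays cover every source sample exactly once.
    """

    client_sets: list[LabeledImageSet]
    client_indices: list[np.ndarray] = field(repr=False)
    n_source: int = 0

    def __post_init__(self) -> None:
        if sum(self.n_k) != self.n:
            raise InputError("client sample counts must sum to the total")

    @property
    def K(self) -> int:
        return len(self.client_sets)

    @property
    def n_k(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.client_sets)

    @property
    def n(self) -> int:
        return self.n_source


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def default_class_specs(n_classes: int, noise_sd: float = 0.1) -> list[ClassSpec]:
    """Well-separated default class templates for ``n_classes`` classes.

    Intensity, radius and ring frequency are cycled over staggered grids
    so that neighbouring classes differ in at least two parameters.  The
    default noise level (sd 0.1 on a unit intensity scale) leaves the
    templates clearly visible, emulating moderate imaging noise.
    """
    if n_classes < 1:
        raise ConfigurationError("n_classes must be >= 1")
    intensities = [0.85, 0.45, 0.70, 0.30, 0.95, 0.55, 0.20, 0.65]
    radii = [0.55, 0.80, 0.35, 0.65, 0.45, 0.90, 0.70, 0.25]
    freqs = [0.0, 2.0, 1.0, 3.0, 2.5, 0.5, 1.5, 3.5]
    return [
        ClassSpec(
            mean_intensity=intensities[c % 8],
            blob_radius_frac=radii[c % 8],
            texture_frequency=freqs[c % 8],
            noise_sd=noise_sd,
        )
        for c in range(n_classes)
    ]


def _class_template(spec: ClassSpec, image_shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic noise-free template of one class."""
    H, W, C = image_shape
    yy = np.linspace(-1.0, 1.0, H)[:, None]
    xx = np.linspace(-1.0, 1.0, W)[None, :]
    dist = np.sqrt(yy**2 + xx**2)
    background = 0.35
    inside = dist <= spec.blob_radius_frac
    ring = 0.18 * np.sin(
        2.0 * np.pi * spec.texture_frequency * dist / max(spec.blob_radius_frac, 1e-9)
    )
    pattern = background + inside * (spec.mean_intensity - background + ring)
    pattern = np.clip(pattern, 0.0, 1.0)
    return np.repeat(pattern[:, :, None], C, axis=2)


def generate_lesion_dataset(
    class_specs: Sequence[ClassSpec],
    counts: Sequence[int],
    image_shape: tuple[int, int, int] = (16, 16, 1),
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> LabeledImageSet:
    """Draw a labeled synthetic lesion dataset.

    Class ``c`` contributes ``counts[c]`` images equal to its template
    plus i.i.d. Gaussian pixel noise of the spec's standard deviation,
    clipped to [0, 1].  Reproducible for a fixed ``seed``.
    """
    if len(class_specs) != len(counts):
        raise ConfigurationError(
            f"got {len(class_specs)} class specs but {len(counts)} counts"
        )
    if any(c < 0 for c in counts):
        raise ConfigurationError("counts must be >= 0")
    H, W, C = image_shape
    if H <= 0 or W <= 0 or C <= 0:
        raise ConfigurationError("image_shape must be positive")
    if class_names is None:
        class_names = [f"C{c}" for c in range(len(class_specs))]
    elif len(class_names) != len(class_specs):
        raise ConfigurationError("one class name per class spec required")

    rng = np.random.default_rng(seed)
    images = np.empty((int(np.sum(counts)), H, W, C), dtype=np.float64)
    labels = np.empty(len(images), dtype=np.int64)
    pos = 0
    for c, (spec, count) in enumerate(zip(class_specs, counts)):
        template = _class_template(spec, (H, W, C))
        for _ in range(count):
            noise = rng.normal(0.0, spec.noise_sd, size=(H, W, C)) if spec.noise_sd else 0.0
            images[pos] = np.clip(template + noise, 0.0, 1.0)
            labels[pos] = c
            pos += 1
    return LabeledImageSet(images, labels, tuple(class_names))


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def _assemble_partition(
    dataset: LabeledImageSet, per_client_indices: list[list[np.ndarray]]
) -> FederatedPartition:
    client_indices = [
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        for chunks in per_client_indices
    ]
    client_sets = [dataset.subset(idx) for idx in client_indices]
    return FederatedPartition(client_sets, client_indices, n_source=len(dataset))


def partition_balanced(
    dataset: LabeledImageSet, K: int, seed: int = 0
) -> FederatedPartition:
    """Stratified near-equal split: per class, client counts differ by <= 1.

    Sample order within each class is shuffled with ``seed``; the
    remainder after integer division goes to the lowest-indexed clients.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[list[np.ndarray]] = [[] for _ in range(K)]
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        rng.shuffle(idx)
        base, rem = divmod(len(idx), K)
        start = 0
        for k in range(K):
            size = base + (1 if k < rem else 0)
            chunks[k].append(idx[start : start + size])
            start += size
    return _assemble_partition(dataset, chunks)


def partition_dirichlet(
    dataset: LabeledImageSet, K: int, concentration: float, seed: int = 0
) -> FederatedPartition:
    """Non-IID split with per-class client shares ~ Dirichlet(concentration).

    Small concentrations concentrate each class on few clients; as
    concentration grows the split approaches the balanced one.  Counts
    are realized by largest-remainder rounding so that each class is
    conserved exactly.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if concentration <= 0:
        raise ConfigurationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    chunks: list[list[np.ndarray]] = [[] for _ in range(K)]
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        rng.shuffle(idx)
        props = rng.dirichlet(np.full(K, concentration))
        raw = props * len(idx)
        counts = np.floor(raw).astype(np.int64)
        shortfall = len(idx) - counts.sum()
        if shortfall:
            # ties broken toward lower client index (stable argsort)
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:shortfall]] += 1
        start = 0
        for k in range(K):
            chunks[k].append(idx[start : start + counts[k]])
            start += counts[k]
    return _assemble_partition(dataset, chunks)


def class_distribution_table(partition: FederatedPartition) -> pd.DataFrame:
    """Per-client, per-class image counts with row and column totals.

    Mirrors the published client-wise distribution table: one row per
    client (1-based ids) plus a ``Total`` row; one column per class plus
    a ``Total`` column.  Column totals reproduce the source dataset's
    per-class counts and the grand total equals the source size.
    """
    if partition.K == 0:
        raise InputError("partition has no clients")
    names = list(partition.client_sets[0].class_names)
    rows = {
        k + 1: partition.client_sets[k].class_counts() for k in range(partition.K)
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names).rename_axis(
        "client"
    )
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


# ---------------------------------------------------------------------------
# Disk interchange
# ---------------------------------------------------------------------------


def save_dataset_png(dataset: LabeledImageSet, directory: str) -> None:
    """Write a dataset as 8-bit PNGs plus a ``manifest.csv``.

    The manifest has columns filename, class_index, class_name.  The
    round trip through :func:`load_dataset_png` is lossless at 8-bit
    quantization.
    """
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class_index", "class_name"])
        writer.writerow(["#classes"] + list(dataset.class_names))
        for i in range(len(dataset)):
            name = f"img_{i:06d}.png"
            arr = np.round(dataset.images[i] * 255.0).astype(np.uint8)
            if arr.shape[2] == 1:
                img = Image.fromarray(arr[:, :, 0], mode="L")
            elif arr.shape[2] == 3:
                img = Image.fromarray(arr, mode="RGB")
            else:
                raise InputError("PNG export supports 1 or 3 channels")
            img.save(os.path.join(directory, name))
            label = int(dataset.labels[i])
            writer.writerow([name, label, dataset.class_names[label]])


def load_dataset_png(directory: str) -> LabeledImageSet:
    """Read a dataset written by :func:`save_dataset_png`."""
    with open(os.path.join(directory, "manifest.csv"), newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        class_row = next(reader)
        class_names = tuple(class_row[1:])
        files, labels = [], []
        for name, label, _ in reader:
            files.append(name)
            labels.append(int(label))
    images = []
    for name in files:
        arr = np.asarray(Image.open(os.path.join(directory, name)), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        images.append(arr / 255.0)
    if images:
        stack = np.stack(images)
    else:
        stack = np.empty((0, 1, 1, 1))
    return LabeledImageSet(stack, np.asarray(labels, dtype=np.int64), class_names)


def save_dataset_npz(dataset: LabeledImageSet, path: str) -> None:
    """Write a dataset as a single compressed array container."""
    np.savez_compressed(
        path,
        images=dataset.images,
        labels=dataset.labels,
        class_names=np.asarray(dataset.class_names, dtype=object),
    )


def load_dataset_npz(path: str) -> LabeledImageSet:
    with np.load(path, allow_pickle=True) as data:
        return LabeledImageSet(
            data["images"], data["labels"], tuple(data["class_names"].tolist())
        )


def save_partition_manifest(partition: FederatedPartition, path: str) -> None:
    """Write the client assignment as CSV (client_id, sample_id, class_index)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["client_id", "sample_id", "class_index"])
        for k, idx in enumerate(partition.client_indices):
            labels = partition.client_sets[k].labels
            for sample_id, label in zip(idx, labels):
                writer.writerow([k, int(sample_id), int(label)])
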