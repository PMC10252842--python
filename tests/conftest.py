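import numpy as np
import pytest

from fedlesion.data import LabeledImageSet, default_class_specs, generate_lesion_dataset
from fedlesion.model import ArchitectureSpec, ConvStage, build_model


@pytest.fixture(scope="session")
def tiny_arch():
    """~71-parameter net, dropout off: cheap finite-difference territory."""
    return ArchitectureSpec(
        input_shape=(6, 6, 1),
        conv_stages=(ConvStage(2, 3, 1),),
        fc_widths=(4,),
        n_classes=3,
        dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """4-class, 30 images/class, 16x16 synthetic lesion set."""
    return generate_lesion_dataset(default_class_specs(4), [30] * 4, (16, 16, 1), seed=11)


def labels_only_dataset(class_counts, seed=0):
    """1x1-pixel dataset: partition bookkeeping depends only on labels."""
    labels = np.repeat(np.arange(len(class_counts)), class_counts)
    images = np.zeros((len(labels), 1, 1, 1))
    names = tuple(f"C{c}" for c in range(len(class_counts)))
    return LabeledImageSet(images, labels, names)
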