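"""CNN forward pass, exact gradients, layer-group split/merge, checkpoints."""

import numpy as np
import pytest

from fedlesion.errors import ConfigurationError, InputError, StructuralError
from fedlesion.model import (
    ArchitectureSpec,
    Batch,
    ConvStage,
    LayeredParameters,
    SHALLOW,
    DEEP,
    build_model,
    default_architecture,
    forward,
    load_checkpoint,
    loss_and_gradient,
    merge_layers,
    save_checkpoint,
    split_layers,
)


def finite_difference_grads(params, batch, eps=1e-6):
    """Central-difference oracle, independent of the backprop path."""
    grads = {}
    for name, arr in params.arrays.items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + eps
            lp, _ = loss_and_gradient(params, batch)
            arr[i] = old - eps
            lm, _ = loss_and_gradient(params, batch)
            arr[i] = old
            num[i] = (lp - lm) / (2 * eps)
        grads[name] = num
    return grads


class TestBuild:
    def test_same_seed_bit_identical(self, tiny_arch):
        a, b = build_model(tiny_arch, 3), build_model(tiny_arch, 3)
        assert all(np.array_equal(a.arrays[k], b.arrays[k]) for k in a.arrays)

    def test_default_architecture_tag_partition(self):
        params = build_model(default_architecture(8), 0)
        assert params.shallow_count > 0 and params.deep_count > 0
        assert params.shallow_count + params.deep_count == params.scalar_count()
        # conv arrays shallow, fc arrays deep
        for name, tag in params.tags.items():
            assert tag == (SHALLOW if name.startswith("conv") else DEEP)

    def test_biases_zero_weights_bounded(self, tiny_arch):
        params = build_model(tiny_arch, 5)
        assert np.array_equal(params.arrays["conv0_b"], np.zeros(2))
        bound = np.sqrt(6.0 / 9)  # fan-in of a 3x3x1 kernel
        assert np.abs(params.arrays["conv0_w"]).max() <= bound

    def test_zero_filter_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            ConvStage(0, 3, 1)

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec((4, 4, 1), (ConvStage(2, 5, 1),), (4,), 2)


class TestForward:
    def test_zero_weights_uniform_probabilities(self, tiny_arch):
        params = build_model(tiny_arch, 0)
        for name in params.arrays:
            params.arrays[name][:] = 0.0
        probs = forward(params, np.random.default_rng(0).random((4, 6, 6, 1)))
        assert np.allclose(probs, 1.0 / 3.0, atol=1e-15)

    def test_softmax_normalization_eight_classes(self):
        arch = default_architecture(8)
        params = build_model(arch, 2)
        probs = forward(params, np.random.default_rng(1).random((5, 16, 16, 1)))
        assert probs.shape == (5, 8)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-12
        assert probs.min() >= 0.0

    def test_hand_computed_two_class_toy(self):
        # 1x1 image, one 1x1 conv filter, direct FC to 2 logits:
        # z = relu(w*x + b); logits = (z*w0 + c0, z*w1 + c1)
        arch = ArchitectureSpec((1, 1, 1), (ConvStage(1, 1, 1),), (), 2, dropout_rate=0.0)
        params = build_model(arch, 0)
        params.arrays["conv0_w"][:] = 2.0
        params.arrays["conv0_b"][:] = 0.5
        params.arrays["fc0_w"][:] = np.array([[1.0, -1.0]])
        params.arrays["fc0_b"][:] = np.array([0.25, 0.0])
        x = np.full((1, 1, 1, 1), 0.6)
        z = 2.0 * 0.6 + 0.5  # 1.7, positive so relu passes
        logits = np.array([z * 1.0 + 0.25, z * -1.0 + 0.0])
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(forward(params, x)[0], expected, atol=1e-14)

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(InputError):
            forward(tiny_model, np.zeros((2, 5, 5, 1)))


class TestLossAndGradient:
    def test_zero_weights_loss_is_log_L(self):
        arch = default_architecture(8)
        params = build_model(arch, 0)
        for name in params.arrays:
            params.arrays[name][:] = 0.0
        batch = Batch(np.random.default_rng(0).random((6, 16, 16, 1)), np.arange(6) % 8)
        loss, _ = loss_and_gradient(params, batch)
        assert loss == pytest.approx(np.log(8.0), abs=1e-12)

    @pytest.mark.parametrize("pooling", ["average", "max"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradients_match_finite_differences(self, pooling, seed):
        arch = ArchitectureSpec(
            (6, 6, 1), (ConvStage(2, 3, 1),), (4,), 3, pooling=pooling, dropout_rate=0.0
        )
        params = build_model(arch, seed)
        rng = np.random.default_rng(seed)
        batch = Batch(rng.random((5, 6, 6, 1)), rng.integers(0, 3, 5))
        _, analytic = loss_and_gradient(params, batch)
        numeric = finite_difference_grads(params, batch)
        for name in analytic:
            denom = np.maximum(np.abs(numeric[name]), 1e-6)
            assert (np.abs(analytic[name] - numeric[name]) / denom).max() < 1e-5

    def test_duplicated_batch_leaves_loss_and_gradient_unchanged(self, tiny_model):
        rng = np.random.default_rng(4)
        images, labels = rng.random((3, 6, 6, 1)), rng.integers(0, 3, 3)
        l1, g1 = loss_and_gradient(tiny_model, Batch(images, labels))
        l2, g2 = loss_and_gradient(
            tiny_model, Batch(np.tile(images, (2, 1, 1, 1)), np.tile(labels, 2))
        )
        assert l1 == pytest.approx(l2, abs=1e-12)
        assert all(np.allclose(g1[k], g2[k], atol=1e-12) for k in g1)

    def test_gradient_shapes_and_tags_congruent(self, tiny_model):
        rng = np.random.default_rng(5)
        _, grads = loss_and_gradient(tiny_model, Batch(rng.random((2, 6, 6, 1)), [0, 1]))
        assert set(grads) == set(tiny_model.arrays)
        assert all(grads[k].shape == tiny_model.arrays[k].shape for k in grads)

    def test_dropout_seed_changes_training_loss_not_eval(self):
        arch = default_architecture(4, dropout_rate=0.5)
        params = build_model(arch, 1)
        rng = np.random.default_rng(2)
        batch = Batch(rng.random((8, 16, 16, 1)), rng.integers(0, 4, 8))
        l_eval1, _ = loss_and_gradient(params, batch, dropout_seed=None)
        l_eval2, _ = loss_and_gradient(params, batch, dropout_seed=None)
        l_tr1, _ = loss_and_gradient(params, batch, dropout_seed=1)
        l_tr2, _ = loss_and_gradient(params, batch, dropout_seed=2)
        assert l_eval1 == l_eval2
        assert l_tr1 != l_tr2  # different masks


class TestSplitMerge:
    def test_round_trip_is_identity(self, tiny_model):
        shallow, deep = split_layers(tiny_model)
        merged = merge_layers(shallow, deep)
        assert all(np.array_equal(merged.arrays[k], tiny_model.arrays[k]) for k in merged.arrays)

    def test_counts_partition_total(self, tiny_model):
        shallow, deep = split_layers(tiny_model)
        assert shallow.scalar_count() + deep.scalar_count() == tiny_model.scalar_count()
        assert shallow.scalar_count() > 0 and deep.scalar_count() > 0

    def test_shallow_group_is_convolutional(self):
        shallow, deep = split_layers(build_model(default_architecture(4), 0))
        assert all(name.startswith("conv") for name in shallow.arrays)
        assert all(name.startswith("fc") for name in deep.arrays)

    def test_chimera_differs_from_both_parents(self, tiny_arch):
        a, b = build_model(tiny_arch, 1), build_model(tiny_arch, 2)
        chimera = merge_layers(split_layers(a)[0], split_layers(b)[1])
        x = np.random.default_rng(3).random((3, 6, 6, 1))
        pa, pb, pc = forward(a, x), forward(b, x), forward(chimera, x)
        assert not np.allclose(pc, pa) and not np.allclose(pc, pb)

    def test_incongruent_groups_rejected(self, tiny_arch):
        other = ArchitectureSpec((6, 6, 1), (ConvStage(3, 3, 1),), (4,), 3, dropout_rate=0.0)
        with pytest.raises(StructuralError):
            merge_layers(split_layers(build_model(tiny_arch, 0))[0],
                         split_layers(build_model(other, 0))[1])

    def test_wrong_shape_array_rejected(self, tiny_arch):
        params = build_model(tiny_arch, 0)
        bad = {k: v.copy() for k, v in params.arrays.items()}
        bad["fc0_w"] = np.zeros((2, 2))
        with pytest.raises(StructuralError):
            LayeredParameters(tiny_arch, bad)


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tiny_model, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        assert back.arch == tiny_model.arch
        assert back.tags == tiny_model.tags
        assert all(np.array_equal(back.arrays[k], tiny_model.arrays[k]) for k in back.arrays)
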