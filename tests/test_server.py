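"""Server round loop: selection, flag schedule, temporal weighting, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedlesion._rng import derive_seed
from fedlesion.client import TrainConfig
from fedlesion.data import default_class_specs, generate_lesion_dataset, partition_balanced
from fedlesion.errors import ConfigurationError, StateError
from fedlesion.model import build_model, split_layers
from fedlesion.server import (
    ClientRecord,
    FederationConfig,
    TrainingHistory,
    RoundRecord,
    exchange_flag,
    rounds_to_accuracy,
    run_async_fl,
    select_clients,
    temporal_weight,
    temporally_weighted_aggregate,
)


def make_records(tiny_arch, values, n_k, staleness, t):
    """Client records whose parameter arrays are constant-filled scalars."""
    records = []
    for k, (v, n, s) in enumerate(zip(values, n_k, staleness)):
        params = build_model(tiny_arch, 0)
        for name in params.arrays:
            params.arrays[name][:] = v
        records.append(
            ClientRecord(
                client_id=k,
                n_k=n,
                timestamp_g=t - s,
                timestamp_s=t - s,
                cached_full=params,
                cached_shallow=split_layers(params)[0],
            )
        )
    return records


def brute_force_weighted_mean(values, n_k, staleness, alpha):
    """Independent oracle: plain-Python normalized weighted sum."""
    n = sum(n_k)
    raw = [(nk / n) * alpha ** (-s) for nk, s in zip(n_k, staleness)]
    total = sum(raw)
    return sum(w * v for w, v in zip(raw, values)) / total


class TestSelectClients:
    def test_full_participation(self):
        assert select_clients(5, 1.0, 0) == (0, 1, 2, 3, 4)

    def test_floor_rule_minimum_one(self):
        assert len(select_clients(5, 0.1, 0)) == 1

    def test_monte_carlo_uniformity(self):
        # K=10, C=0.5: each client should appear in ~50% of draws
        K, draws = 10, 10000
        counts = np.zeros(K)
        for seed in range(draws):
            for k in select_clients(K, 0.5, seed):
                counts[k] += 1
        p = 0.5
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.abs(counts - draws * p).max() < 3 * sigma

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            select_clients(5, 0.0, 0)
        with pytest.raises(ConfigurationError):
            select_clients(5, 1.5, 0)


class TestExchangeFlag:
    def test_period_one_always_full(self):
        assert all(exchange_flag(t, 1) == 1 for t in range(1, 20))

    def test_modular_convention(self):
        assert exchange_flag(5, 5) == 1
        assert exchange_flag(3, 5) == 0

    def test_full_round_count_over_horizon(self):
        flags = [exchange_flag(t, 2) for t in range(1, 11)]
        assert sum(flags) == 5


class TestTemporalWeight:
    def test_fresh_weight_is_one(self):
        assert temporal_weight(7, 7, 1.5) == 1.0

    def test_closed_form(self):
        assert temporal_weight(4, 2, 2.0) == pytest.approx(0.25)

    @given(
        ts=st.integers(0, 50),
        dt1=st.integers(0, 20),
        dt2=st.integers(0, 20),
        alpha=st.floats(1.01, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_staleness_composes_multiplicatively(self, ts, dt1, dt2, alpha):
        t, t2 = ts + dt1, ts + dt1 + dt2
        left = temporal_weight(t, ts, alpha) * temporal_weight(t2, t, alpha)
        assert left == pytest.approx(temporal_weight(t2, ts, alpha), rel=1e-12)

    def test_future_timestamp_rejected(self):
        with pytest.raises(StateError):
            temporal_weight(3, 4, 2.0)

    def test_alpha_at_most_one_rejected(self):
        with pytest.raises(ConfigurationError):
            temporal_weight(3, 2, 1.0)


class TestAggregate:
    def test_all_fresh_equals_fedavg_weighting(self, tiny_arch):
        values, n_k = [1.0, 3.0, 5.0], [10, 20, 30]
        records = make_records(tiny_arch, values, n_k, [0, 0, 0], t=4)
        out = temporally_weighted_aggregate(records, 4, 2.0, "full")
        expected = np.average(values, weights=n_k)
        for arr in out.values():
            assert np.allclose(arr, expected, atol=1e-12)

    def test_hand_computed_staleness_case(self, tiny_arch):
        # scalars (4, 8, 2), n=(1,1,2), staleness (0,1,1), alpha=2:
        # raw weights (0.25, 0.125, 0.25) -> normalized (0.4, 0.2, 0.4)
        # -> 0.4*4 + 0.2*8 + 0.4*2 = 4.0
        records = make_records(tiny_arch, [4.0, 8.0, 2.0], [1, 1, 2], [0, 1, 1], t=5)
        out = temporally_weighted_aggregate(records, 5, 2.0, "full")
        for arr in out.values():
            assert np.allclose(arr, 4.0, atol=1e-12)

    def test_single_client_returns_its_cache_regardless_of_staleness(self, tiny_arch):
        records = make_records(tiny_arch, [3.5], [7], [9], t=10)
        out = temporally_weighted_aggregate(records, 10, 1.8, "full")
        for arr in out.values():
            assert np.allclose(arr, 3.5, atol=1e-12)

    @given(
        n_clients=st.integers(1, 6),
        alpha=st.floats(1.05, 4.0),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, tiny_arch, n_clients, alpha, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 3, n_clients).tolist()
        n_k = rng.integers(1, 50, n_clients).tolist()
        staleness = rng.integers(0, 8, n_clients).tolist()
        t = 20
        records = make_records(tiny_arch, values, n_k, staleness, t)
        out = temporally_weighted_aggregate(records, t, alpha, "full")
        expected = brute_force_weighted_mean(values, n_k, staleness, alpha)
        for arr in out.values():
            assert np.allclose(arr, expected, rtol=1e-12, atol=1e-12)

    def test_convex_combination_bound(self, tiny_arch):
        values = [-2.0, 0.5, 7.0]
        records = make_records(tiny_arch, values, [5, 1, 3], [2, 0, 4], t=8)
        out = temporally_weighted_aggregate(records, 8, 1.5, "full")
        for arr in out.values():
            assert arr.min() >= min(values) - 1e-12
            assert arr.max() <= max(values) + 1e-12

    def test_staleness_monotonicity(self, tiny_arch):
        # increasing one client's staleness strictly decreases its pull
        # toward its own value
        base = make_records(tiny_arch, [10.0, 0.0], [1, 1], [0, 0], t=9)
        staler = make_records(tiny_arch, [10.0, 0.0], [1, 1], [3, 0], t=9)
        fresh = temporally_weighted_aggregate(base, 9, 2.0, "full")["conv0_w"].flat[0]
        decayed = temporally_weighted_aggregate(staler, 9, 2.0, "full")["conv0_w"].flat[0]
        assert decayed < fresh

    def test_shallow_mode_aggregates_shallow_group_only(self, tiny_arch):
        records = make_records(tiny_arch, [1.0, 2.0], [1, 1], [0, 0], t=3)
        out = temporally_weighted_aggregate(records, 3, 2.0, "shallow")
        assert set(out) == set(records[0].cached_shallow.arrays)


@pytest.fixture(scope="module")
def tiny_world():
    data = generate_lesion_dataset(default_class_specs(3), [12] * 3, (6, 6, 1), seed=17)
    eval_set = generate_lesion_dataset(default_class_specs(3), [4] * 3, (6, 6, 1), seed=18)
    partition = partition_balanced(data, 3, seed=19)
    return partition, eval_set


class TestRunAsyncFL:
    def test_zero_rounds_history_empty_model_is_u0(self, tiny_arch, tiny_world):
        partition, eval_set = tiny_world
        fed = FederationConfig(clients=3, rounds=0, es_period=2, seed=5)
        hist = run_async_fl(fed, TrainConfig(epochs=1, batch_size=6, lr=0.01),
                            partition, eval_set, tiny_arch)
        assert len(hist) == 0
        u0 = build_model(tiny_arch, derive_seed(5, "init"))
        assert all(
            np.array_equal(hist.final_params.arrays[k], u0.arrays[k]) for k in u0.arrays
        )

    def test_fixed_seed_runs_are_bit_identical(self, tiny_arch, tiny_world):
        partition, eval_set = tiny_world
        fed = FederationConfig(clients=3, fraction=0.67, rounds=6, es_period=2, seed=9)
        cfg = TrainConfig(epochs=1, batch_size=6, lr=0.02)
        h1 = run_async_fl(fed, cfg, partition, eval_set, tiny_arch)
        h2 = run_async_fl(fed, cfg, partition, eval_set, tiny_arch)
        assert h1.to_dataframe().equals(h2.to_dataframe())
        assert all(
            np.array_equal(h1.final_params.arrays[k], h2.final_params.arrays[k])
            for k in h1.final_params.arrays
        )

    def test_history_has_one_entry_per_round_with_flag_schedule(self, tiny_arch, tiny_world):
        partition, eval_set = tiny_world
        fed = FederationConfig(clients=3, rounds=6, es_period=3, seed=1)
        hist = run_async_fl(fed, TrainConfig(epochs=1, batch_size=6, lr=0.01),
                            partition, eval_set, tiny_arch)
        assert [r.round for r in hist.records] == [1, 2, 3, 4, 5, 6]
        assert [r.flag for r in hist.records] == [0, 0, 1, 0, 0, 1]

    def test_shallow_rounds_move_less_traffic(self, tiny_arch, tiny_world):
        partition, eval_set = tiny_world
        fed = FederationConfig(clients=3, rounds=4, es_period=2, seed=2)
        hist = run_async_fl(fed, TrainConfig(epochs=1, batch_size=6, lr=0.01),
                            partition, eval_set, tiny_arch)
        model = hist.final_params
        for rec in hist.records:
            expected = 3 * (model.scalar_count() if rec.flag else model.shallow_count)
            assert rec.uplink_scalars == expected == rec.downlink_scalars

    def test_empty_client_is_skipped_not_fatal(self, tiny_arch):
        data = generate_lesion_dataset(default_class_specs(3), [10, 10, 0], (6, 6, 1), seed=3)
        partition = partition_balanced(data, 2, seed=0)
        # hand-build a partition with an empty third client
        from fedlesion.data import FederatedPartition, LabeledImageSet

        empty = LabeledImageSet(np.zeros((0, 6, 6, 1)), np.zeros(0, dtype=int),
                                data.class_names)
        partition = FederatedPartition(
            partition.client_sets + [empty],
            partition.client_indices + [np.empty(0, dtype=np.int64)],
            n_source=len(data),
        )
        eval_set = generate_lesion_dataset(default_class_specs(3), [3] * 3, (6, 6, 1), seed=4)
        fed = FederationConfig(clients=3, rounds=3, es_period=1, seed=0)
        hist = run_async_fl(fed, TrainConfig(epochs=1, batch_size=10, lr=0.01),
                            partition, eval_set, tiny_arch)
        assert len(hist) == 3  # no crash, all rounds logged


class TestRoundsToAccuracy:
    def _history(self, accs):
        hist = TrainingHistory()
        for i, a in enumerate(accs, start=1):
            hist.records.append(RoundRecord(i, 1, (0,), 0.0, a, 0, 0, 0.0))
        return hist

    def test_monotone_history(self):
        assert rounds_to_accuracy(self._history([0.2, 0.5, 0.9]), 0.9) == 3

    def test_target_above_max_gives_sentinel(self):
        assert rounds_to_accuracy(self._history([0.2, 0.5]), 0.9) is None

    def test_vacuous_target_zero(self):
        assert rounds_to_accuracy(self._history([0.2, 0.5]), 0.0) == 1
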