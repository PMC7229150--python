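import numpy as np
import pytest
from scipy.linalg import hankel

from diybot.ssa import (
    aggregate_blocks,
    signal_strength,
    ssa_decompose,
    ssa_group,
    ssa_reconstruct,
    ssa_smooth,
    wcorrelation_matrix,
)
from diybot.timeseries import UniformTimeSeries


def ts_of(x, step=1.0, name="x"):
    return UniformTimeSeries(np.asarray(x, dtype=float), step=step, channels=[name])


class TestAggregateBlocks:
    def test_constant_series(self):
        out = aggregate_blocks(ts_of(np.full(100, 3.5)), 10.0)
        assert out.n == 10
        assert np.all(out.values == 3.5)

    def test_block_equal_step_is_identity(self):
        ts = ts_of(np.arange(20.0))
        out = aggregate_blocks(ts, 1.0)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_direct_mean_oracle(self, rng):
        # independent oracle: plain mean over the first block
        x = rng.normal(size=1000)
        out = aggregate_blocks(ts_of(x, step=0.01), 1.0)  # blocks of 100
        assert out.n == 10
        assert out.values[0, 0] == pytest.approx(x[:100].mean(), rel=1e-12)
        assert out.step == 1.0

    def test_trailing_partial_block_discarded(self):
        out = aggregate_blocks(ts_of(np.arange(25.0)), 10.0)
        assert out.n == 2

    def test_block_below_step_rejected(self):
        with pytest.raises(ValueError, match="below the sampling step"):
            aggregate_blocks(ts_of(np.arange(10.0), step=2.0), 1.0)

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError, match="not a multiple"):
            aggregate_blocks(ts_of(np.arange(10.0)), 2.5)

    def test_commutes_with_channel_selection(self, rng):
        vals = rng.normal(size=(60, 2))
        ts = UniformTimeSeries(vals, step=1.0, channels=["a", "b"])
        left = aggregate_blocks(ts, 5.0).single("b")
        right = aggregate_blocks(ts.single("b"), 5.0)
        np.testing.assert_allclose(left.values, right.values, rtol=1e-14)


class TestDecompose:
    def test_constant_series_rank_one(self):
        d = ssa_decompose(ts_of(np.full(40, 2.0)), 10)
        assert d.singular_values[0] > 1e-8
        assert np.all(d.singular_values[1:] < 1e-10)

    def test_sinusoid_rank_two_oracle(self):
        # oracle: numpy matrix rank of the trajectory matrix itself
        n, P = 200, 20
        x = np.sin(2 * np.pi * np.arange(n) / P)
        L = 2 * P
        X = hankel(x[:L], x[L - 1:])
        assert np.linalg.matrix_rank(X, tol=1e-8) == 2
        d = ssa_decompose(ts_of(x), L)
        assert np.sum(d.singular_values > 1e-8 * d.singular_values[0]) == 2
        # the two nonzero singular values are nearly equal
        assert d.singular_values[1] / d.singular_values[0] > 0.95

    def test_white_noise_leading_strength_small(self, rng):
        strengths = []
        for _ in range(5):
            d = ssa_decompose(ts_of(rng.normal(size=300)))
            strengths.append(d.component_strengths()[0])
        assert np.max(strengths) < 50.0

    def test_singular_values_sorted_nonnegative(self, rng):
        d = ssa_decompose(ts_of(rng.normal(size=100)))
        s = d.singular_values
        assert np.all(s >= 0)
        assert np.all(np.diff(s) <= 1e-12)

    def test_orthonormal_vector_families(self, rng):
        d = ssa_decompose(ts_of(rng.normal(size=120)), 30)
        for M in (d.left_vectors, d.right_vectors):
            np.testing.assert_allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-8)

    def test_window_bounds(self):
        with pytest.raises(ValueError, match="window_length"):
            ssa_decompose(ts_of(np.arange(20.0)), 11)
        with pytest.raises(ValueError, match="window_length"):
            ssa_decompose(ts_of(np.arange(20.0)), 1)

    def test_multichannel_rejected(self):
        ts = UniformTimeSeries(np.ones((10, 2)), 1.0, ["a", "b"])
        with pytest.raises(ValueError, match="single channel"):
            ssa_decompose(ts)


class TestGrouping:
    def test_explicit_all_indices_full_strength(self, rng):
        d = ssa_decompose(ts_of(rng.normal(size=80)))
        d = ssa_group(d, {"everything": list(range(d.n_components))})
        assert signal_strength(d, "everything") == pytest.approx(100.0, abs=1e-6)

    def test_non_partition_rejected(self, rng):
        d = ssa_decompose(ts_of(rng.normal(size=40)))
        with pytest.raises(ValueError, match="twice"):
            ssa_group(d, {"a": [0, 1], "b": [1, 2]})

    def test_auto_groups_sinusoid_pair(self, rng):
        # oracle: the w-correlation matrix itself pairs components 0 and 1
        n = 400
        x = np.sin(2 * np.pi * np.arange(n) / 20) + 0.05 * rng.normal(size=n)
        d = ssa_decompose(ts_of(x))
        wc = np.abs(wcorrelation_matrix(d, 6))
        assert wc[0, 1] > 0.5
        d = ssa_group(d, "wcorr")
        assert sorted(d.groups["signal"]) == [0, 1]

    def test_two_sinusoids_two_groups(self):
        n = 600
        t = np.arange(n)
        x = 2.0 * np.sin(2 * np.pi * t / 30) + 1.0 * np.sin(2 * np.pi * t / 7)
        d = ssa_group(ssa_decompose(ts_of(x)), "wcorr")
        assert sorted(d.groups["signal"]) == [0, 1]
        assert sorted(d.groups["signal_2"]) == [2, 3]


class TestReconstruct:
    def test_completeness_identity(self, rng):
        # full-partition reconstruction returns the input to 1e-9 relative
        x = rng.normal(size=250) * 3 + 1.0
        d = ssa_decompose(ts_of(x))
        d = ssa_group(d, {"all": list(range(d.n_components))})
        rec = ssa_reconstruct(d, "all").values[:, 0]
        assert np.abs(rec - x).max() / np.abs(x).max() < 1e-9

    def test_completeness_over_auto_groups(self, rng):
        x = np.sin(2 * np.pi * np.arange(300) / 25) + 0.1 * rng.normal(size=300)
        d = ssa_group(ssa_decompose(ts_of(x)), "wcorr")
        total = np.zeros(300)
        for label in d.groups:
            total += ssa_reconstruct(d, label).values[:, 0]
        assert np.abs(total - x).max() / np.abs(x).max() < 1e-9

    def test_signal_reconstruction_beats_noise_floor(self, rng):
        clean = np.sin(2 * np.pi * np.arange(500) / 25)
        noise_sd = 0.3
        x = clean + noise_sd * rng.normal(size=500)
        d = ssa_group(ssa_decompose(ts_of(x)), "wcorr")
        rec = ssa_reconstruct(d, "signal").values[:, 0]
        rmse = np.sqrt(np.mean((rec - clean) ** 2))
        assert rmse < noise_sd

    def test_constant_series_leading_group(self):
        d = ssa_decompose(ts_of(np.full(30, 4.0)), 5)
        d = ssa_group(d, {"lead": [0]})
        rec = ssa_reconstruct(d, "lead").values[:, 0]
        np.testing.assert_allclose(rec, 4.0, atol=1e-10)

    def test_unknown_group_rejected(self, rng):
        d = ssa_group(ssa_decompose(ts_of(rng.normal(size=60))), "wcorr")
        with pytest.raises(KeyError, match="nope"):
            ssa_reconstruct(d, "nope")

    def test_fft_path_matches_direct_path(self, rng):
        # same group summed component-wise vs batched FFT reconstruction
        x = rng.normal(size=120)
        d = ssa_decompose(ts_of(x))
        idx = list(range(12))
        direct = np.zeros(120)
        for i in idx:
            direct += d.elementary_series(i)
        d = ssa_group(d, {"g": idx, "rest": list(range(12, d.n_components))})
        fft_based = ssa_reconstruct(d, "g").values[:, 0]
        np.testing.assert_allclose(fft_based, direct, atol=1e-10)


class TestSignalStrength:
    def test_single_complete_group(self, rng):
        d = ssa_decompose(ts_of(rng.normal(size=50)))
        d = ssa_group(d, {"g": list(range(d.n_components))})
        assert signal_strength(d, "g") == pytest.approx(100.0)

    def test_equal_split_symmetry(self):
        # two equal singular values split 50/50: a pure sinusoid's pair
        x = np.sin(2 * np.pi * np.arange(400) / 20)
        d = ssa_decompose(ts_of(x), 40)
        d = ssa_group(d, {"a": [0], "b": [1]})
        assert signal_strength(d, "a") == pytest.approx(50.0, abs=1.0)

    def test_variance_decomposition_oracle(self, rng):
        # strength of the signal group ~ signal variance fraction
        clean = np.sqrt(2) * np.sin(2 * np.pi * np.arange(2000) / 40)  # var 1
        noise_sd = 0.5
        x = clean + noise_sd * rng.normal(size=2000)
        expected = 100 * 1.0 / (1.0 + noise_sd**2)
        d = ssa_group(ssa_decompose(ts_of(x)), "wcorr")
        assert signal_strength(d, "signal") == pytest.approx(expected, abs=5.0)

    def test_zero_series_rejected(self):
        d = ssa_decompose(ts_of(np.zeros(20)), 5)
        d = ssa_group(d, {"g": [0]})
        with pytest.raises(ValueError, match="all-zero"):
            signal_strength(d, "g")

    def test_strengths_sum_to_100(self, rng):
        d = ssa_group(ssa_decompose(ts_of(rng.normal(size=90))), "wcorr")
        total = sum(signal_strength(d, g) for g in d.groups)
        assert total == pytest.approx(100.0, abs=1e-6)


def test_ssa_smooth_denoises(rng):
    clean = np.sin(2 * np.pi * np.arange(400) / 25)
    x = clean + 0.2 * rng.normal(size=400)
    ts = UniformTimeSeries(np.column_stack([x, -x]), 1.0, ["a", "b"])
    sm = ssa_smooth(ts)
    assert np.sqrt(np.mean((sm.values[:, 0] - clean) ** 2)) < 0.1
    assert sm.channels == ["a", "b"]
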