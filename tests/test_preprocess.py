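import numpy as np
import pytest

from varselbench.dataset import Dataset
from varselbench.preprocess import (
    autoscale,
    dedup_perfect_correlation,
    filter_low_variation,
    spike_random_variables,
    split_train_test,
)


def make_pair(X, y=None, seed=0):
    n = X.shape[0]
    y = np.arange(n, dtype=float) if y is None else y
    ds = Dataset(X=X, y=y, names=[f"c{i}" for i in range(X.shape[1])])
    return split_train_test(ds, 0.7, seed)


class TestSplit:
    def test_sizes_and_disjointness(self, rng):
        ds = Dataset(
            X=rng.standard_normal((1000, 3)), y=rng.standard_normal(1000),
            names=["a", "b", "c"],
        )
        pair = split_train_test(ds, 0.7, seed=3)
        assert pair.train.n_samples == 700 and pair.test.n_samples == 300
        seen = {tuple(row) for row in pair.train.X} | {tuple(row) for row in pair.test.X}
        assert len(seen) == 1000  # disjoint sample sets

    def test_same_seed_identical(self, rng):
        ds = Dataset(X=rng.standard_normal((10, 2)), y=np.arange(10.0), names=["a", "b"])
        p1 = split_train_test(ds, 0.7, seed=9)
        p2 = split_train_test(ds, 0.7, seed=9)
        np.testing.assert_array_equal(p1.train.y, p2.train.y)

    def test_different_seeds_differ(self, rng):
        # oracle: the two permutations' leading 7-subsets are compared directly
        ds = Dataset(X=rng.standard_normal((10, 2)), y=np.arange(10.0), names=["a", "b"])
        m1 = set(split_train_test(ds, 0.7, seed=0).train.y)
        m2 = set(split_train_test(ds, 0.7, seed=1).train.y)
        e1 = set(np.random.default_rng(0).permutation(10)[:7].astype(float))
        e2 = set(np.random.default_rng(1).permutation(10)[:7].astype(float))
        assert m1 == e1 and m2 == e2 and m1 != m2

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.3])
    def test_bad_fraction(self, frac, tiny_dataset):
        with pytest.raises(ValueError):
            split_train_test(tiny_dataset, frac, 0)

    def test_too_few_samples(self):
        ds = Dataset(X=np.ones((3, 1)) * [[1], [2], [3]], y=np.arange(3.0), names=["a"])
        with pytest.raises(ValueError):
            split_train_test(ds, 0.5, 0)


class TestLowVariationFilter:
    def test_mode_frequency_at_threshold_dropped(self, rng):
        # hand count: the mode of the train column occurs 8/10 = 0.8 >= 0.8
        from varselbench.dataset import SplitPair

        col = np.array([1, 1, 1, 1, 1, 1, 1, 1, 2, 3], dtype=float)
        names = ["modal", "varied"]
        train = Dataset(
            X=np.column_stack([col, np.arange(10.0)]), y=np.arange(10.0), names=names
        )
        test = Dataset(
            X=rng.standard_normal((5, 2)), y=np.arange(5.0), names=names
        )
        out = filter_low_variation(SplitPair(train=train, test=test, seed=0), 0.8)
        assert out.train.names == ["varied"]
        assert out.test.names == ["varied"]  # decided on train, applied to both

    def test_distinct_values_kept_constant_dropped(self, rng):
        X = np.column_stack([rng.permutation(20).astype(float), np.full(20, 5.0), rng.normal(size=20)])
        ds = Dataset(X=X, y=np.arange(20.0), names=["distinct", "const", "noise"])
        out = filter_low_variation(split_train_test(ds, 0.7, 0), 0.8)
        assert out.train.names == ["distinct", "noise"]

    def test_idempotent(self, rng):
        pair = make_pair(rng.standard_normal((30, 4)))
        once = filter_low_variation(pair, 0.8)
        twice = filter_low_variation(once, 0.8)
        assert once.train.names == twice.train.names

    def test_all_dropped_errors(self):
        X = np.column_stack([np.full(20, 1.0), np.full(20, 2.0)])
        ds = Dataset(X=X, y=np.arange(20.0), names=["a", "b"])
        with pytest.raises(ValueError, match="threshold"):
            filter_low_variation(split_train_test(ds, 0.7, 0), 0.8)


class TestDedup:
    def test_scaled_copy_dropped_first_kept(self, rng):
        a = rng.standard_normal(30)
        X = np.column_stack([a, 2 * a, -a, rng.standard_normal(30)])
        pair = make_pair(X)
        out = dedup_perfect_correlation(pair)
        assert out.train.names == ["c0", "c3"]

    def test_noisy_copy_kept(self, rng):
        a = rng.standard_normal(40)
        b = a + rng.normal(scale=0.2, size=40)
        pair = make_pair(np.column_stack([a, b]))
        r = abs(np.corrcoef(pair.train.X, rowvar=False)[0, 1])
        assert r < 1 - 1e-12  # the oracle the filter must agree with
        out = dedup_perfect_correlation(pair)
        assert out.train.names == ["c0", "c1"]

    def test_idempotent(self, rng):
        a = rng.standard_normal(30)
        pair = make_pair(np.column_stack([a, 2 * a, rng.standard_normal(30)]))
        once = dedup_perfect_correlation(pair)
        twice = dedup_perfect_correlation(once)
        assert once.train.names == twice.train.names


class TestSpike:
    def test_doubles_columns_with_probe_flags(self, rng):
        pair = make_pair(rng.standard_normal((40, 10)))
        out = spike_random_variables(pair, seed=4)
        assert out.train.n_vars == 20
        assert out.train.probe_mask.sum() == 10
        assert out.test.probe_mask.sum() == 10
        np.testing.assert_array_equal(out.train.X[:, :10], pair.train.X)

    def test_same_seed_identical_probes(self, rng):
        pair = make_pair(rng.standard_normal((40, 5)))
        o1 = spike_random_variables(pair, seed=1)
        o2 = spike_random_variables(pair, seed=1)
        np.testing.assert_array_equal(o1.train.X, o2.train.X)
        np.testing.assert_array_equal(o1.test.X, o2.test.X)

    def test_probes_uncorrelated_with_y(self, rng):
        n = 500
        X = rng.standard_normal((n, 10))
        y = X[:, 0] + rng.normal(size=n)
        ds = Dataset(X=X, y=y, names=[f"x{i}" for i in range(10)])
        pair = split_train_test(ds, 0.7, 0)
        out = spike_random_variables(pair, seed=2)
        probes = out.train.X[:, out.train.probe_mask]
        ytr = out.train.y
        r = [abs(np.corrcoef(probes[:, j], ytr)[0, 1]) for j in range(probes.shape[1])]
        assert max(r) < 3 / np.sqrt(out.train.n_samples)

    def test_reserved_prefix_collision(self, rng):
        X = rng.standard_normal((20, 2))
        ds = Dataset(X=X, y=np.arange(20.0), names=["RANDPROBE_1", "b"])
        with pytest.raises(ValueError, match="RANDPROBE"):
            spike_random_variables(split_train_test(ds, 0.7, 0), 0)


class TestAutoscale:
    def test_train_stats_and_inverse(self, rng):
        pair = make_pair(rng.standard_normal((50, 3)) * 5 + 2, y=rng.normal(3, 2, 50))
        out = autoscale(pair)
        np.testing.assert_allclose(out.train.X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.train.X.std(axis=0, ddof=1), 1, rtol=1e-12)
        np.testing.assert_allclose(out.inverse_y(out.train.y), pair.train.y)

    def test_test_partition_uses_train_stats(self, rng):
        pair = make_pair(rng.standard_normal((50, 3)), y=rng.normal(size=50))
        out = autoscale(pair)
        # scaled with TRAIN statistics, so the test mean is generally nonzero
        assert np.abs(out.test.X.mean(axis=0)).max() > 1e-6

    def test_zero_variance_errors(self):
        X = np.column_stack([np.arange(20.0), np.full(20, 3.0)])
        ds = Dataset(X=X, y=np.arange(20.0), names=["a", "b"])
        with pytest.raises(ValueError, match="standard deviation"):
            autoscale(split_train_test(ds, 0.7, 0))
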