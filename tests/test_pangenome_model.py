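import itertools
import math

import numpy as np
import pytest

from panpav import pangenome_model as pm
from panpav.io_formats import PavMatrix
from oracles import subset_pan_core


class TestCountCombinations:
    @pytest.mark.parametrize("n,k,want", [(10, 1, 10), (10, 10, 1),
                                          (10, 5, 252), (0, 0, 1)])
    def test_values(self, n, k, want):
        assert pm.count_combinations(n, k) == want
        # direct factorial evaluation
        assert want == math.factorial(n) // (math.factorial(k)
                                             * math.factorial(n - k))

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            pm.count_combinations(3, 4)


class TestSubsetCounts:
    TOY = PavMatrix(["a", "b", "c"], ["L1", "L2", "L3"],
                    [[1, 1, 1], [1, 0, 0], [0, 1, 1]])

    def test_hand_enumerated_pair(self):
        pan, core, _ = pm.subset_counts(self.TOY, ["L1", "L2"])
        assert (pan, core) == (3, 1)

    def test_single_line(self):
        pan, core, new = pm.subset_counts(self.TOY, ["L1"])
        assert pan == core == new == 2

    def test_full_subset_core(self):
        truth = PavMatrix([f"g{i}" for i in range(100)], ["A", "B", "C"],
                          np.vstack([np.ones((80, 3), int),
                                     np.eye(3, dtype=int)[
                                         np.arange(20) % 3]]))
        pan, core, _ = pm.subset_counts(truth, ["A", "B", "C"])
        assert core == 80 and pan == 100

    def test_new_genes_for_ordered_addition(self):
        _, _, new = pm.subset_counts(self.TOY, ["L2", "L1"])
        assert new == 1  # only "b" is new with L1 added after L2

    def test_unknown_line(self):
        with pytest.raises(ValueError, match="unknown"):
            pm.subset_counts(self.TOY, ["L9"])

    def test_matches_brute_force_on_all_subsets(self, rng):
        arr = rng.integers(0, 2, size=(40, 6))
        arr[:, 0] |= arr.sum(axis=1) == 0  # no all-zero rows
        lines = [f"L{i}" for i in range(6)]
        pav = PavMatrix([f"g{i}" for i in range(40)], lines, arr)
        for k in range(1, 7):
            for combo in itertools.combinations(range(6), k):
                pan, core, _ = pm.subset_counts(pav,
                                                [lines[i] for i in combo])
                assert (pan, core) == subset_pan_core(arr, list(combo))


class TestBuildCurve:
    def test_all_core_constant_pan(self):
        pav = PavMatrix([f"g{i}" for i in range(30)],
                        ["A", "B", "C", "D"], np.ones((30, 4), int))
        curve = pm.build_curve(pav)
        assert np.allclose(curve.pan_means, 30)
        assert np.allclose(curve.core_means, 30)

    def test_disjoint_lines_linear_pan(self):
        # each of 4 lines carries 5 unique genes -> pan mean = 5k
        arr = np.zeros((20, 4), int)
        for j in range(4):
            arr[5 * j:5 * (j + 1), j] = 1
        pav = PavMatrix([f"g{i}" for i in range(20)],
                        ["A", "B", "C", "D"], arr)
        curve = pm.build_curve(pav)
        assert np.allclose(curve.pan_means, 5 * np.arange(1, 5))

    def test_all_subsets_counts(self, rng):
        arr = rng.integers(0, 2, size=(25, 10))
        arr[:, 0] = 1
        pav = PavMatrix([f"g{i}" for i in range(25)],
                        [f"L{i}" for i in range(10)], arr)
        curve = pm.build_curve(pav)
        n_subsets = sum(len(curve.pan_sizes[k]) for k in curve.k_values)
        assert n_subsets == 2 ** 10 - 1 == 1023

    def test_monotone_means_on_random_matrices(self, rng):
        for _ in range(5):
            arr = rng.integers(0, 2, size=(30, 6))
            arr[:, 2] = 1
            pav = PavMatrix([f"g{i}" for i in range(30)],
                            [f"L{i}" for i in range(6)], arr)
            curve = pm.build_curve(pav)
            assert (np.diff(curve.pan_means) >= -1e-9).all()
            assert (np.diff(curve.core_means) <= 1e-9).all()

    def test_refuses_exhaustive_blowup(self):
        arr = np.ones((5, 16), int)
        pav = PavMatrix([f"g{i}" for i in range(5)],
                        [f"L{i}" for i in range(16)], arr)
        with pytest.raises(ValueError, match="sampled"):
            pm.build_curve(pav)

    def test_sampled_mode_deterministic(self, rng):
        arr = rng.integers(0, 2, size=(30, 8))
        arr[:, 0] = 1
        pav = PavMatrix([f"g{i}" for i in range(30)],
                        [f"L{i}" for i in range(8)], arr)
        c1 = pm.build_curve(pav, mode="sampled", max_subsets=10, seed=4)
        c2 = pm.build_curve(pav, mode="sampled", max_subsets=10, seed=4)
        assert c1.pan_sizes == c2.pan_sizes


class TestFits:
    def test_power_law_exact_recovery(self):
        x = np.arange(1, 11, dtype=float)
        y = 200 * x ** 0.6 + 50
        fit = pm.fit_power_law(x, y)
        assert abs(fit.A - 200) / 200 < 1e-6
        assert abs(fit.B - 0.6) / 0.6 < 1e-6
        assert abs(fit.C - 50) / 50 < 1e-6

    def test_exponential_exact_recovery(self):
        x = np.arange(1, 11, dtype=float)
        y = 300 * np.exp(-0.4 * x) + 100
        fit = pm.fit_exponential(x, y)
        assert abs(fit.A - 300) / 300 < 1e-6
        assert abs(fit.B + 0.4) / 0.4 < 1e-6
        assert abs(fit.C - 100) / 100 < 1e-6

    def test_constant_data_degenerate(self):
        x = np.arange(1, 8, dtype=float)
        fit = pm.fit_power_law(x, np.full_like(x, 42.0))
        pred = fit.predicted(x)
        assert np.allclose(pred, 42.0, atol=1e-6)

    def test_decreasing_power_law(self):
        x = np.arange(1, 11, dtype=float)
        y = 500 * x ** -0.8 + 30
        fit = pm.fit_power_law(x, y)
        assert abs(fit.B + 0.8) < 1e-5

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pm.fit_power_law([1, 2, 3], [1, 2, 3])


class TestExtrapolate:
    def test_interpolation_consistency(self):
        x = np.arange(1, 11, dtype=float)
        y = 200 * x ** 0.6 + 50
        fit = pm.fit_power_law(x, y)
        pred, _ = pm.extrapolate(fit, 10)
        assert abs(pred - y[-1]) < 1e-6

    def test_closed_pangenome_prediction(self, rng):
        # finite 1000-gene pool, each line samples 65% of it
        pool, n_lines = 1000, 10
        arr = (rng.random((pool, n_lines)) < 0.65).astype(int)
        arr[arr.sum(axis=1) == 0, 0] = 1
        pav = PavMatrix([f"g{i}" for i in range(pool)],
                        [f"L{i}" for i in range(n_lines)], arr)
        curve = pm.build_curve(pav, seed=1)
        fit = pm.fit_power_law(curve.k_values, curve.pan_means)
        pred, _ = pm.extrapolate(fit, 50)
        assert abs(pred - pool) / pool < 0.02

    def test_exponential_asymptote(self):
        x = np.arange(1, 11, dtype=float)
        y = 300 * np.exp(-0.4 * x) + 100
        fit = pm.fit_exponential(x, y)
        pred, _ = pm.extrapolate(fit, 200)
        assert abs(pred - 100) < 1e-3

    def test_se_positive_with_noise(self, rng):
        x = np.arange(1, 11, dtype=float)
        y = 200 * x ** 0.6 + 50 + rng.normal(0, 2, size=10)
        fit = pm.fit_power_law(x, y)
        pred, se = pm.extrapolate(fit, 20)
        assert se > 0


class TestNewGeneCurve:
    def test_first_step_mean_row_presence(self, rng):
        arr = rng.integers(0, 2, size=(40, 5))
        arr[:, 0] = 1
        pav = PavMatrix([f"g{i}" for i in range(40)],
                        [f"L{i}" for i in range(5)], arr)
        curve = pm.new_gene_curve(pav, n_orders=400, seed=2)
        assert curve.shape == (5,)
        # first step = genes in the first line of a random order
        expect = arr.sum(axis=0).mean()
        assert abs(curve[0] - expect) < 3.0
        # total over steps always equals pan size
        assert abs(curve.sum() - (arr.sum(axis=1) > 0).sum()) < 1e-9
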