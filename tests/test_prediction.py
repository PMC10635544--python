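import numpy as np
import pandas as pd
import pytest

import uvkinet as uk

from oracles import naive_outer


def random_network(n, rng, scale=0.3):
    """Random symmetric weight matrix with realistic-looking r values."""
    A = rng.normal(size=(n, n)) * scale
    W = np.clip((A + A.T) / 2, -0.999, 0.999)
    np.fill_diagonal(W, 1.0)
    return uk.WeightedNetwork([f"g{i:02d}" for i in range(n)], W)


def clique_network(n_module=10, n_background=20, bg_scale=0.05, seed=0):
    """Planted perfect clique: module pairs at r = 1, background near 0."""
    rng = np.random.default_rng(seed)
    m = n_module + n_background
    A = rng.normal(size=(m, m)) * bg_scale
    W = np.clip((A + A.T) / 2, -0.2, 0.2)
    W[:n_module, :n_module] = 1.0
    np.fill_diagonal(W, 1.0)
    ids = [f"mod{i:02d}" for i in range(n_module)] + \
          [f"bg{i:02d}" for i in range(n_background)]
    return uk.WeightedNetwork(ids, W)


class TestRankWithTies:
    @pytest.mark.parametrize("scores,expected", [
        ([5, 3, 1], [1, 2, 3]),
        ([5, 3, 3, 1], [1, 2.5, 2.5, 4]),
        ([2, 2, 2, 2], [2.5, 2.5, 2.5, 2.5]),  # all equal: (m+1)/2 each
    ])
    def test_fractional_ranks(self, scores, expected):
        s = pd.Series(scores, index=[f"g{i}" for i in range(len(scores))])
        assert uk.rank_with_ties(s).tolist() == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            uk.rank_with_ties(pd.Series([1.0, np.nan]))


class TestDetectOutlier:
    def _traces(self, rows):
        grid = np.round(np.linspace(0.1, 0.9, 5), 3)
        return pd.DataFrame(rows, columns=grid).rename(
            index=lambda i: f"s{i}")

    def test_constant_high_trace_detected(self):
        tr = self._traces([[450] * 5, [50] * 5, [80] * 5])
        assert uk.detect_outlier(tr) == "s0"

    def test_single_good_threshold_disqualifies(self):
        tr = self._traces([[450, 450, 150, 450, 450], [50] * 5, [80] * 5])
        assert uk.detect_outlier(tr) is None

    def test_largest_maximum_wins(self):
        tr = self._traces([[300] * 5, [250, 250, 450, 250, 250], [50] * 5])
        assert uk.detect_outlier(tr) == "s1"


class TestMedianOptimalThreshold:
    def test_odd_length_is_central_value(self):
        assert uk.median_optimal_threshold([0.93, 0.946, 0.95]) == 0.946

    def test_even_length_mean_snapped_to_grid(self):
        assert uk.median_optimal_threshold([0.90, 0.92]) == pytest.approx(0.91)

    def test_single_value(self):
        assert uk.median_optimal_threshold([0.5]) == pytest.approx(0.5)

    def test_snap_tie_goes_to_smaller_grid_value(self):
        grid = np.array([0.4, 0.6])
        assert uk.median_optimal_threshold([0.4, 0.6], grid) == pytest.approx(0.4)


class TestInnerLoocv:
    def test_grid_of_length_one(self):
        net = clique_network()
        seeds = [f"mod{i:02d}" for i in range(4)]
        res = uk.inner_loocv(net, seeds, grid=np.array([0.5]))
        assert res.optimal_tau == 0.5

    def test_perfect_clique_rank_is_tie_group_mean_and_tau_smallest(self):
        # all module genes tie at the top at every threshold below 1, so the
        # mean trace is flat and the argmin tie rule yields the smallest tau
        net = clique_network(n_module=8, n_background=22, bg_scale=0.04)
        seeds = [f"mod{i:02d}" for i in range(5)]
        grid = uk.threshold_grid(0.30, 0.90, 0.05)
        res = uk.inner_loocv(net, seeds, grid)
        assert res.optimal_tau == pytest.approx(0.30)
        # held-out seed ties with the 3 other non-scoring module genes at
        # score 4: tie group of 4 -> fractional rank (1+2+3+4)/4 = 2.5
        assert np.allclose(res.traces.to_numpy(), 2.5)

    def test_uncorrelated_seeds_rank_near_half_pool(self):
        rng = np.random.default_rng(8)
        net = random_network(80, rng, scale=0.15)
        seeds = [f"g{i:02d}" for i in range(0, 40, 8)]
        res = uk.inner_loocv(net, seeds, uk.threshold_grid(0.05, 0.95, 0.05))
        mean_rank = res.traces.to_numpy().mean()
        pool = net.n_genes - (len(seeds) - 1)
        assert abs(mean_rank - pool / 2) < pool * 0.2

    def test_too_few_training_seeds(self):
        net = clique_network()
        with pytest.raises(ValueError):
            uk.inner_loocv(net, ["mod00", "mod01"], np.array([0.5]))


class TestOuterLoocvAgainstBruteForce:
    @pytest.mark.parametrize("instance_seed", range(20))
    def test_matches_independent_reimplementation(self, instance_seed):
        rng = np.random.default_rng(instance_seed)
        n = int(rng.integers(12, 21))
        n_seeds = 4
        net = random_network(n, rng, scale=0.45)
        seeds = list(np.asarray(net.gene_ids)[
            rng.choice(n, size=n_seeds, replace=False)])
        grid = np.round(np.linspace(0.05, 0.95, 21), 6)
        # low outlier cap so the outlier branch is exercised on small pools
        res = uk.outer_loocv(net, seeds, grid, outlier_rank=5.0)
        folds, median_rank = naive_outer(net.weights, net.gene_ids, seeds,
                                         grid, rank_cap=5.0)
        for got, exp in zip(res.folds, folds):
            assert got.test_seed == exp[0]
            assert got.optimal_tau == pytest.approx(exp[1])
            assert got.test_rank == pytest.approx(exp[2])
            assert (got.excluded_outlier or None) == exp[3]
        assert res.median_rank == pytest.approx(median_rank)

    def test_gene_order_exchangeability(self):
        rng = np.random.default_rng(5)
        net = random_network(25, rng, scale=0.4)
        seeds = ["g01", "g07", "g13", "g19", "g23"]
        grid = np.round(np.linspace(0.1, 0.9, 9), 6)
        res = uk.outer_loocv(net, seeds, grid)
        perm = rng.permutation(25)
        net_p = uk.WeightedNetwork(
            [net.gene_ids[i] for i in perm],
            net.weights[np.ix_(perm, perm)])
        res_p = uk.outer_loocv(net_p, seeds, grid)
        assert {f.test_seed: f.test_rank for f in res.folds} == \
               {f.test_seed: f.test_rank for f in res_p.folds}


class TestFinalPrediction:
    def test_zero_noise_top50_equals_true_neighbors(self, zero_noise_network):
        _, truth, net = zero_noise_network
        res = uk.nested_prediction(net, truth.seeds,
                                   k=len(truth.true_neighbors))
        assert set(res.top_k) == set(truth.true_neighbors)

    def test_k_equal_to_pool_returns_everything(self):
        net = clique_network(n_module=6, n_background=10)
        seeds = [f"mod{i:02d}" for i in range(6)]
        res = uk.final_prediction(net, seeds, tau=0.5, k=10)
        assert len(res.top_k) == 10
        assert set(res.ranking["gene_id"]) == set(res.top_k)

    def test_k_exceeding_pool_rejected(self):
        net = clique_network(n_module=6, n_background=10)
        with pytest.raises(ValueError, match="pool"):
            uk.final_prediction(net, [f"mod{i:02d}" for i in range(6)],
                                tau=0.5, k=11)

    def test_output_order_is_deterministic(self):
        net = clique_network(n_module=6, n_background=10, bg_scale=0.0)
        seeds = [f"mod{i:02d}" for i in range(5)]
        res = uk.final_prediction(net, seeds, tau=0.5, k=3)
        df = res.ranking
        assert (df["score"].is_monotonic_decreasing)
        # ties broken by gene id ascending
        for s in df["score"].unique():
            block = df[df["score"] == s]["gene_id"].tolist()
            assert block == sorted(block)

    def test_planted_instance_regression(self, planted_instance):
        """Frozen outcome of the default noisy study at generator seed 7."""
        _, _, truth, _, net = planted_instance
        res = uk.nested_prediction(net, truth.seeds)
        hits = sum(g in set(truth.true_neighbors) for g in res.top_k)
        assert res.median_tau == pytest.approx(0.988)
        assert res.observed_median_rank == pytest.approx(17.5)
        assert hits == 44


class TestPermutationTest:
    def test_determinism(self, planted_instance):
        _, _, truth, _, net = planted_instance
        a = uk.permutation_test(net, truth.seeds, B=199, rng_seed=5, tau=0.98)
        b = uk.permutation_test(net, truth.seeds, B=199, rng_seed=5, tau=0.98)
        assert a.observed == b.observed and a.p == b.p
        assert np.array_equal(a.null_statistics, b.null_statistics)

    def test_perfect_module_achieves_add_one_floor(self):
        net = clique_network(n_module=12, n_background=60, bg_scale=0.05)
        seeds = [f"mod{i:02d}" for i in range(8)]
        res = uk.permutation_test(net, seeds, B=99, rng_seed=1, tau=0.5)
        assert res.p == pytest.approx(1 / 100)
        assert res.n_leq == 0

    def test_p_bounds(self):
        rng = np.random.default_rng(0)
        net = random_network(40, rng)
        res = uk.permutation_test(net, ["g00", "g01", "g02", "g03", "g04"],
                                  B=49, rng_seed=2, tau=0.3)
        assert 1 / 50 <= res.p <= 1.0

    def test_null_seeds_give_calibrated_p(self):
        # seeds drawn from the null: p should be roughly uniform
        rng = np.random.default_rng(10)
        net = random_network(60, rng, scale=0.25)
        hits = 0
        draw_rng = np.random.default_rng(123)
        for rep in range(200):
            seeds = list(np.asarray(net.gene_ids)[
                draw_rng.choice(60, size=5, replace=False)])
            res = uk.permutation_test(net, seeds, B=99, rng_seed=rep, tau=0.3)
            if res.p <= 0.05:
                hits += 1
        assert 0.01 < hits / 200 < 0.12

    def test_nested_policy_matches_outer_loocv_observed(self):
        net = clique_network(n_module=8, n_background=16, bg_scale=0.1)
        seeds = [f"mod{i:02d}" for i in range(5)]
        grid = np.round(np.linspace(0.1, 0.9, 9), 6)
        outer = uk.outer_loocv(net, seeds, grid)
        res = uk.permutation_test(net, seeds, B=19, rng_seed=3,
                                  tau_policy="nested", grid=grid)
        assert res.observed == pytest.approx(outer.median_rank)

    def test_pool_smaller_than_seed_count_rejected(self):
        net = clique_network(n_module=3, n_background=1)
        with pytest.raises(ValueError):
            uk.permutation_test(net, net.gene_ids, B=9, rng_seed=0, tau=0.5)
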