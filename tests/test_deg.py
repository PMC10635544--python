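import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import uvkinet as uk
from uvkinet.io_formats import FormatError

from conftest import make_design, make_matrix


class TestLowIntensityFilter:
    def test_gene_below_pooled_quantile_everywhere_is_removed(self):
        # gene "dim" sits at ~1 in all 21 samples; nine other genes sit near
        # 100, so the pooled 20th percentile lies far above "dim"
        genes = {f"g{i}": {} for i in range(9)}
        genes["dim"] = {(g, w): [1.0, 1.1, 1.2] for g in ("control", "uv")
                        for w in (1, 2, 4, 6, 8)}
        m = make_matrix(genes)
        pooled = np.sort(m.data.to_numpy().ravel())
        assert np.quantile(pooled, 0.20) > 1.2  # fixture sanity, by sorting
        retained = uk.low_intensity_filter(m, 0.20)
        assert "dim" not in retained and len(retained) == 9

    def test_one_bright_sample_rescues_gene(self):
        genes = {f"g{i}": {} for i in range(9)}
        # dim everywhere except one uv week-8 replicate
        genes["dim"] = {(g, w): [1.0, 1.1, 1.2] for g in ("control", "uv")
                        for w in (1, 2, 4, 6, 8)}
        genes["dim"][("uv", 8)] = [1.0, 1.1, 500.0]
        m = make_matrix(genes)
        assert "dim" in uk.low_intensity_filter(m, 0.20)

    def test_fraction_zero_removes_nothing(self):
        m = make_matrix({"a": {}, "b": {("uv", 6): [1.0, 1.0, 1.0]}})
        assert uk.low_intensity_filter(m, 0.0) == ["a", "b"]


class TestControlDrift:
    @pytest.mark.parametrize("m8,excluded", [(160.0, True), (140.0, False)])
    def test_threshold_at_1_5_fold(self, m8, excluded):
        m = make_matrix({"g": {("control", 1): [100.0] * 3,
                               ("control", 8): [m8] * 3}})
        out = uk.control_drift_genes(m, fold=1.5)
        assert ("g" in out) == excluded

    def test_symmetric_in_direction(self):
        m = make_matrix({"g": {("control", 1): [160.0] * 3,
                               ("control", 8): [100.0] * 3}})
        assert uk.control_drift_genes(m) == ["g"]

    def test_zero_control_mean_is_an_error(self):
        m = make_matrix({"g": {("control", 8): [0.0, 0.0, 0.0]}})
        with pytest.raises(FormatError, match="'g'"):
            uk.control_drift_genes(m)

    def test_requires_week8_controls(self):
        m = make_matrix({"g": {}}, design=make_design(control_week8=False))
        with pytest.raises(FormatError, match="week 8"):
            uk.control_drift_genes(m)


class TestFoldChange:
    @pytest.mark.parametrize("uv_mean,expected", [(400.0, 2.0), (25.0, -2.0),
                                                  (100.0, 0.0)])
    def test_log2_ratio_vs_week1_control(self, uv_mean, expected):
        m = make_matrix({"g": {("control", 1): [100.0] * 3,
                               ("uv", 6): [uv_mean] * 3}})
        profiles = uk.fold_change_profiles(m)
        assert profiles.loc["g", 6] == pytest.approx(expected)

    def test_nonpositive_mean_is_an_error(self):
        m = make_matrix({"g": {("uv", 6): [0.0, 0.0, 0.0]}})
        with pytest.raises(FormatError, match="uv week-6"):
            uk.fold_change_profiles(m)


class TestPerWeekTest:
    def test_identical_groups_give_p_one(self):
        m = make_matrix({"g": {("control", 1): [100.0] * 3,
                               ("uv", 6): [100.0] * 3}})
        assert uk.per_week_test(m).loc["g", 6] == 1.0

    def test_clear_separation_matches_welch_by_hand(self):
        # log2 uv = {9.9, 10.0, 10.1} vs log2 ctrl = {7.9, 8.0, 8.1}:
        # t = 2 / sqrt(0.01/3 + 0.01/3) ~= 24.49, df ~= 4, p << 0.001
        m = make_matrix({"g": {("control", 1): [2 ** 7.9, 2 ** 8.0, 2 ** 8.1],
                               ("uv", 6): [2 ** 9.9, 2 ** 10.0, 2 ** 10.1]}})
        p = uk.per_week_test(m).loc["g", 6]
        assert p < 0.001
        from scipy import stats
        expected = 2 * stats.t.sf(2 / np.sqrt(2 * 0.01 / 3), df=4)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_two_sided_symmetry_under_label_swap(self):
        m_up = make_matrix({"g": {("control", 1): [99.0, 100.0, 101.0],
                                  ("uv", 6): [198.0, 200.0, 202.0]}})
        m_dn = make_matrix({"g": {("control", 1): [198.0, 200.0, 202.0],
                                  ("uv", 6): [99.0, 100.0, 101.0]}})
        p_up = uk.per_week_test(m_up).loc["g", 6]
        p_dn = uk.per_week_test(m_dn).loc["g", 6]
        assert p_up == pytest.approx(p_dn, rel=1e-9)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert uk.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        # q_(i) = min_{j>=i} m p_(j)/j = (0.04, 0.04, 0.04, 0.04)
        q = uk.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_equal_ps_stay_put(self):
        assert np.allclose(uk.bh_adjust([0.5] * 7), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            uk.bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_dominates_p_and_is_order_invariant(self, ps):
        p = np.array(ps)
        q = uk.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(uk.bh_adjust(p[perm]), q[perm])


class TestSelectDegs:
    def _cascade_fixture(self):
        """Seven genes engineered to hit every branch of the cascade."""
        genes = {
            "up_a": {("uv", 6): [398.0, 400.0, 402.0]},          # log2fc 2
            "up_b": {("uv", 2): [798.0, 800.0, 802.0]},          # log2fc 3
            "dn_a": {("uv", 6): [24.0, 25.0, 26.0]},             # log2fc ~ -2
            "dn_b": {("uv", 8): [12.0, 12.5, 13.0]},             # log2fc ~ -3
            "dn_c": {("uv", 4): [49.0, 50.0, 51.0]},             # log2fc ~ -1
            "ns": {("uv", 6): [185.0, 186.6, 188.0]},            # |log2fc| < 1
            "drifty": {("control", 8): [198.0, 200.0, 202.0],
                       ("uv", 8): [398.0, 400.0, 402.0]},
        }
        return make_matrix(genes)

    def test_expected_counts_per_branch(self):
        deg = uk.run_deg_pipeline(self._cascade_fixture())
        c = deg.counts()
        assert c["up"] == 2 and c["down"] == 3
        assert c["not_significant"] == 1 and c["excluded_drift"] == 1

    def test_below_twofold_everywhere_is_not_a_deg(self):
        weeks = [1, 2, 4, 6, 8]
        profiles = pd.DataFrame([[0.9] * 5], index=["g"], columns=weeks)
        q = pd.DataFrame([[0.0] * 5], index=["g"], columns=weeks)
        deg = uk.select_degs(profiles, q, q, [], [])
        assert deg.table.loc["g", "direction"] == "not_significant"

    def test_drift_exclusion_precedes_selection(self):
        weeks = [1, 2, 4, 6, 8]
        profiles = pd.DataFrame([[3.0] * 5], index=["g"], columns=weeks)
        q = pd.DataFrame([[0.0] * 5], index=["g"], columns=weeks)
        deg = uk.select_degs(profiles, q, q, ["g"], [])
        assert deg.table.loc["g", "direction"] == "excluded_drift"

    def test_direction_from_largest_qualifying_week(self):
        weeks = [1, 2, 4, 6, 8]
        # week 8 has the largest |fc| but is not significant; week 2 (down)
        # is the largest qualifying week
        profiles = pd.DataFrame([[0.0, -1.5, 1.2, 0.0, 4.0]], index=["g"],
                                columns=weeks)
        q = pd.DataFrame([[1.0, 0.01, 0.01, 1.0, 0.9]], index=["g"],
                         columns=weeks)
        deg = uk.select_degs(profiles, q, q, [], [])
        assert deg.table.loc["g", "direction"] == "down"

    def test_cascade_is_monotone(self):
        m = self._cascade_fixture()
        deg = uk.run_deg_pipeline(m)
        n_excluded = (deg.table["direction"]
                      .isin(["excluded_drift", "excluded_low_intensity"]).sum())
        n_selected = len(deg.up_genes) + len(deg.down_genes)
        assert n_selected <= m.n_genes - n_excluded

    def test_table_round_trip(self, tmp_path):
        deg = uk.run_deg_pipeline(self._cascade_fixture())
        deg.to_tsv(tmp_path / "deg.tsv")
        back = uk.DEGTable.from_tsv(tmp_path / "deg.tsv")
        assert back.counts() == deg.counts()
        assert np.allclose(back.profiles().to_numpy(),
                           deg.profiles().to_numpy())
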