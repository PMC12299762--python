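"""Membership D-values, CDC/WDC and Deng gray relational analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germscreen import (
    cdc,
    d_value,
    evaluate,
    gra_weights,
    gray_relational_analysis,
    gray_relational_degree,
    indicator_ranking,
    membership,
    wdc,
)


class TestMembership:
    def test_basic_column(self):
        mu = membership(pd.DataFrame({"x": [2.0, 0.0, -2.0]}))
        assert list(mu["x"]) == [1.0, 0.5, 0.0]

    def test_extremes_map_to_zero_and_one(self, ev_rep1):
        mu = ev_rep1.membership
        assert np.allclose(mu.min(), 0.0) and np.allclose(mu.max(), 1.0)
        assert ((mu.to_numpy() >= 0) & (mu.to_numpy() <= 1)).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(min_value=-50, max_value=50),
           st.floats(min_value=0.01, max_value=20))
    def test_affine_invariance(self, shift, scale):
        x = pd.DataFrame({"x": [0.3, -1.2, 4.5, 2.2]})
        assert np.allclose(membership(x), membership(x * scale + shift))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            membership(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestDValue:
    def test_unit_and_zero_rows(self):
        mu = pd.DataFrame([[1.0, 1, 1], [0, 0, 0], [0.5, 0.5, 0.5]])
        d = d_value(mu, [0.692, 0.189, 0.119])
        assert np.allclose(d, [1.0, 0.0, 0.5])

    def test_weighted_single_component(self):
        mu = pd.DataFrame([[1.0, 0.0, 0.0]])
        d = d_value(mu, [0.692, 0.189, 0.119])
        assert d.iloc[0] == pytest.approx(0.692)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d_value(pd.DataFrame([[0.5, 0.5]]), [1.0])

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            d_value(pd.DataFrame([[0.5, 0.5]]), [0.9, 0.9])


class TestCDCAndWDC:
    def test_cdc_is_row_mean(self):
        dc = pd.DataFrame({"a": [1.0, 0.4], "b": [1.0, 0.6]})
        assert np.allclose(cdc(dc), [1.0, 0.5])

    def test_cdc_missing_flagged(self):
        dc = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 0.6]})
        assert np.isnan(cdc(dc).iloc[1])

    def test_cdc_permutation_invariant(self):
        row = pd.DataFrame([[0.4, 0.6, 0.5, 0.9]])
        shuffled = row[[2, 0, 3, 1]]
        assert cdc(row).iloc[0] == pytest.approx(cdc(shuffled).iloc[0])

    def test_wdc_unit_row(self):
        dc = pd.DataFrame([[1.0, 1.0, 1.0]])
        assert wdc(dc, [0.5, 0.3, 0.2]).iloc[0] == pytest.approx(1.0)

    def test_wdc_equal_weights_equals_cdc(self, dc_rep1):
        w = np.full(8, 1 / 8)
        assert np.allclose(wdc(dc_rep1, w), cdc(dc_rep1), equal_nan=True)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=7),
           st.floats(min_value=0.01, max_value=1.0))
    def test_wdc_monotone_in_any_dc(self, col, bump):
        rng = np.random.default_rng(42)
        dc = pd.DataFrame(rng.uniform(0, 2, size=(5, 8)))
        w = gra_weights(rng.uniform(0.3, 1.0, 8)).to_numpy()
        bumped = dc.copy()
        bumped.iloc[:, col] += bump
        assert (wdc(bumped, w) >= wdc(dc, w) - 1e-12).all()


class TestGRA:
    def test_hand_computed_deng_example(self):
        # ref [1,2,3] vs comp [3,2,1], rho 0.5, raw sequences:
        # deltas [2,0,2] -> xi [1/3, 1, 1/3] -> gamma 5/9.
        g = gray_relational_degree([1, 2, 3], [3, 2, 1], rho=0.5,
                                   normalization="none")
        assert g == pytest.approx(5 / 9, abs=1e-12)

    def test_reference_against_itself(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = rng.uniform(0, 5, 10)
            assert gray_relational_degree(seq, seq) == pytest.approx(1.0)

    def test_coefficients_in_unit_interval(self, dc_rep1, ev_rep1):
        gra = gray_relational_analysis(ev_rep1.scores["D"], dc_rep1)
        xi = gra.coefficients.to_numpy()
        assert ((xi > 0) & (xi <= 1)).all()
        assert ((gra.degrees > 0) & (gra.degrees <= 1)).all()

    def test_permutation_of_elements(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 1, 12)
        comp = rng.uniform(0, 1, 12)
        perm = rng.permutation(12)
        g1 = gray_relational_degree(ref, comp)
        g2 = gray_relational_degree(ref[perm], comp[perm])
        assert g1 == pytest.approx(g2)

    def test_degenerate_all_equal(self):
        comps = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        gra = gray_relational_analysis([1, 2, 3], comps,
                                       normalization="none")
        assert np.allclose(gra.degrees, 1.0)

    @pytest.mark.parametrize("rho", [0.0, 1.5, -0.2])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            gray_relational_degree([1, 2], [2, 1], rho=rho)

    def test_delta_scope_option(self, dc_rep1, ev_rep1):
        d = ev_rep1.scores["D"]
        g_global = gray_relational_analysis(d, dc_rep1).degrees
        g_per = gray_relational_analysis(
            d, dc_rep1, delta_scope="per_comparison").degrees
        assert not np.allclose(g_global, g_per)


class TestWeightsAndRanking:
    def test_equal_degrees(self):
        assert np.allclose(gra_weights(np.full(8, 0.7)), 1 / 8)

    def test_normalization_and_scaling(self):
        w = gra_weights([0.9, 0.1])
        assert np.allclose(w, [0.9, 0.1])
        assert np.allclose(gra_weights([0.45, 0.05]), w)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gra_weights([0.5, 0.0])

    def test_ranking_shape_and_self_reference(self, dc_rep1, ev_rep1):
        tab = indicator_ranking(dc_rep1, ev_rep1.scores)
        assert tab.shape == (8, 6)
        for name in ("D", "WDC", "CDC"):
            assert sorted(tab[f"{name}_rank"]) == list(range(1, 9))

    def test_column_matching_reference_ranks_first(self):
        rng = np.random.default_rng(5)
        ref = np.linspace(0, 1, 30)
        dc = pd.DataFrame({"match": 2.0 * ref + 1.0,
                           "noise1": rng.uniform(0, 1, 30),
                           "noise2": rng.uniform(0, 1, 30)})
        scores = pd.DataFrame({"D": ref})
        tab = indicator_ranking(dc, scores)
        assert tab.loc["match", "D_degree"] == pytest.approx(1.0)
        assert tab.loc["match", "D_rank"] == 1

    def test_reversed_column_scores_lower(self):
        ref = np.linspace(0, 1, 25)
        dc = pd.DataFrame({"up": ref.copy(), "down": ref[::-1].copy()})
        gra = gray_relational_analysis(ref, dc)
        assert gra.degrees["up"] > gra.degrees["down"]


class TestEvaluate:
    def test_score_table(self, ev_rep1):
        s = ev_rep1.scores
        assert list(s.columns) == ["D", "WDC", "CDC"]
        assert ((s["D"] >= 0) & (s["D"] <= 1)).all()
        assert ev_rep1.pca_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert ev_rep1.gra_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_three_scores_strongly_concordant(self, ev_rep1):
        # The composite scores are alternative summaries of the same DC
        # structure and must rank accessions nearly identically.
        s = ev_rep1.scores
        assert s.corr(method="spearman").min().min() >= 0.8
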