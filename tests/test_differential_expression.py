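"""NB exact test, dispersion estimation, BH-FDR and companion statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sagescape.containers import GeneCountMatrix
from sagescape.differential_expression import (
    DOWN,
    NS,
    UP,
    annotate_significance,
    bh_adjust,
    chisq_2x2,
    classify_population_specific,
    equalize_library_sizes,
    estimate_dispersion,
    exact_test,
    mann_whitney,
)


def _cm(values, libs=None):
    arr = np.asarray(values)
    libs = libs or [f"L{i}" for i in range(arr.shape[1])]
    return GeneCountMatrix(raw=pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=libs))


class TestExactTest:
    def test_matches_exact_binomial_at_zero_dispersion(self):
        rng = np.random.default_rng(1)
        m = _cm(rng.poisson(40, size=(40, 8)))
        a = [f"L{i}" for i in range(4)]
        b = [f"L{i}" for i in range(4, 8)]
        table = exact_test(m, a, b, dispersion=0.0)
        eq = equalize_library_sizes(m.raw)
        for gene in m.gene_ids:
            sa = int(eq.loc[gene, a].sum())
            z = int(eq.loc[gene].sum())
            expected = stats.binomtest(sa, z, len(a) / 8).pvalue
            assert table.loc[gene, "p_value"] == pytest.approx(expected,
                                                               abs=1e-9)

    def test_symmetric_counts_give_p_one(self):
        m = _cm([[5, 7, 7, 5]])
        table = exact_test(m, ["L0", "L1"], ["L2", "L3"], dispersion=0.3)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_conditional_enumeration(self):
        """Small totals: conditional NB null enumerated via scipy pmf."""
        phi = 0.5
        r = 1 / phi
        n_a = n_b = 2
        for sa, sb in [(0, 10), (3, 7), (12, 4), (15, 15), (1, 29)]:
            z = sa + sb
            # filler gene keeps library totals equal so equalization is a no-op
            top = max(sa, sb) + 5
            filler = [top - sa, top, top - sb, top]
            m = _cm([[sa, 0, sb, 0], filler])
            table = exact_test(m, ["L0", "L1"], ["L2", "L3"], dispersion=phi)
            weights = np.array([
                stats.nbinom.pmf(a, n_a * r, 0.4)
                * stats.nbinom.pmf(z - a, n_b * r, 0.4)
                for a in range(z + 1)
            ])
            weights /= weights.sum()
            p_ref = weights[weights <= weights[sa] * (1 + 1e-8)].sum()
            assert table["p_value"].iloc[0] == pytest.approx(min(1.0, p_ref),
                                                             rel=1e-6)

    def test_zero_total_gene_defined(self):
        m = _cm([[0, 0, 0, 0], [3, 1, 2, 4]])
        table = exact_test(m, ["L0", "L1"], ["L2", "L3"], dispersion=0.1)
        assert table["p_value"].iloc[0] == 1.0
        assert table["log2fc"].iloc[0] == 0.0

    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        m = _cm(rng.poisson(25, size=(20, 8)))
        a = [f"L{i}" for i in range(4)]
        b = [f"L{i}" for i in range(4, 8)]
        t_ab = exact_test(m, a, b, dispersion=0.2)
        t_ba = exact_test(m, b, a, dispersion=0.2)
        np.testing.assert_allclose(t_ab["p_value"], t_ba["p_value"],
                                   rtol=1e-9)
        np.testing.assert_allclose(t_ab["log2fc"], -t_ba["log2fc"],
                                   atol=1e-9)

    def test_overlapping_groups_rejected(self):
        m = _cm([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            exact_test(m, ["L0", "L1"], ["L1", "L2"])

    def test_power_at_fourfold_change(self):
        """Genes at a true 4-fold change (mu 100, phi 0.2, 4 vs 4) are
        detected at FDR < 0.05 in over 80% of cases."""
        rng = np.random.default_rng(3)
        r = 1 / 0.2
        n_true = 100  # half up in group A, half up in group B: library
        # totals stay balanced, so equalization does not dilute the effect
        null = rng.negative_binomial(r, r / (r + 100), size=(800, 8))
        up_a = np.hstack([
            rng.negative_binomial(r, r / (r + 400), size=(n_true // 2, 4)),
            rng.negative_binomial(r, r / (r + 100), size=(n_true // 2, 4)),
        ])
        up_b = np.hstack([
            rng.negative_binomial(r, r / (r + 100), size=(n_true // 2, 4)),
            rng.negative_binomial(r, r / (r + 400), size=(n_true // 2, 4)),
        ])
        m = _cm(np.vstack([null, up_a, up_b]))
        a = [f"L{i}" for i in range(4)]
        b = [f"L{i}" for i in range(4, 8)]
        table = annotate_significance(exact_test(m, a, b, dispersion=0.2))
        hits = (table.iloc[800:]["fdr"] < 0.05).mean()
        assert hits > 0.8


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(4)
        m = _cm(rng.poisson(80, size=(1500, 8)))
        groups = {f"L{i}": ("a" if i < 4 else "b") for i in range(8)}
        est = estimate_dispersion(m, groups, tagwise=False)
        assert est.common_dispersion < 0.05

    def test_recovers_simulated_dispersion(self):
        rng = np.random.default_rng(5)
        phi = 0.4
        r = 1 / phi
        m = _cm(rng.negative_binomial(r, r / (r + 100), size=(2000, 8)))
        groups = {f"L{i}": ("a" if i < 4 else "b") for i in range(8)}
        est = estimate_dispersion(m, groups, tagwise=False)
        assert 0.3 <= est.common_dispersion <= 0.5

    def test_huge_shrinkage_pulls_tagwise_to_common(self):
        rng = np.random.default_rng(6)
        r = 1 / 0.3
        m = _cm(rng.negative_binomial(r, r / (r + 60), size=(300, 8)))
        groups = {f"L{i}": ("a" if i < 4 else "b") for i in range(8)}
        est = estimate_dispersion(m, groups, shrinkage_weight=1e7)
        spread = np.abs(np.log10(est.tagwise_dispersion + 1e-9)
                        - np.log10(est.common_dispersion + 1e-9))
        assert spread.max() < 0.1

    def test_all_zero_matrix_rejected(self):
        m = _cm(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError):
            estimate_dispersion(m, {f"L{i}": "a" for i in range(4)})


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.05], [0.05]),
        ([0.001, 0.5, 0.9, 1.0], [0.004, 1.0, 1.0, 1.0]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        reference = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), reference, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_order_equivariance(self, p):
        p = np.asarray(p)
        perm = np.random.RandomState(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]),
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassification:
    def _table(self, directions, fdrs):
        genes = [f"g{i}" for i in range(len(directions))]
        return pd.DataFrame(
            {"log2fc": [1.0 if d == UP else -1.0 if d == DOWN else 0.1
                        for d in directions],
             "p_value": fdrs, "fdr": fdrs, "direction": directions},
            index=genes)

    def test_lake_only_up(self):
        lake = self._table([UP, UP], [0.01, 0.01])
        river = self._table([NS, UP], [0.6, 0.02])
        sets = classify_population_specific(lake, river)
        assert sets.lake_only_up == {"g0"}
        assert sets.shared_up == {"g1"}
        assert "g1" not in sets.lake_only_up

    def test_empty_tables_empty_sets(self):
        empty = self._table([], [])
        sets = classify_population_specific(empty, empty)
        assert not (sets.lake_only_up | sets.river_only_down | sets.shared_up)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            classify_population_specific(self._table([UP], [0.01]),
                                         self._table([UP, NS], [0.01, 0.5]))


class TestChisq:
    def test_hand_computed_statistic(self):
        chi2, p = chisq_2x2([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_independent_table_zero(self):
        chi2, p = chisq_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_proportional_rows_zero(self):
        chi2, _ = chisq_2x2([[7, 3], [7, 3]])
        assert chi2 == pytest.approx(0.0)

    def test_matches_scipy_without_correction(self):
        table = [[16, 2], [2, 16]]
        chi2, p = chisq_2x2(table)
        ref = stats.chi2_contingency(np.asarray(table), correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 3]])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_p_matches_enumeration(self):
        """Brute force over all labelings of the pooled sample."""
        a = [1.2, 3.4, 5.6, 2.2]
        b = [4.1, 7.7, 0.3]
        u_obs, p = mann_whitney(a, b)
        pooled = sorted(a + b)
        n_a = len(a)

        def u_stat(a_vals, b_vals):
            return sum(1 for x in a_vals for y in b_vals if x > y)

        us = [u_stat(c, [x for x in pooled if x not in c])
              for c in itertools.combinations(pooled, n_a)]
        lower = sum(1 for u in us if u <= u_obs) / len(us)
        upper = sum(1 for u in us if u >= u_obs) / len(us)
        assert p == pytest.approx(min(1.0, 2 * min(lower, upper)))

    def test_identical_groups_maximal_p(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0] * 4, [1.0, 2.0, 3.0, 4.0] * 4)
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=10)
        _, p = mann_whitney(a + 1000, rng.normal(size=10))
        assert p < 0.001
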