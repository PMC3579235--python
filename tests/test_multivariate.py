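"""Correlation distance, PerMANOVA and NMDS ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sagescape import synthetic_data as syn
from sagescape.containers import GeneCountMatrix, SampleMeta
from sagescape.multivariate import (
    DistanceMatrix,
    correlation_distance,
    nmds,
    permanova,
)


def _matrix(values, libs=None):
    arr = np.asarray(values, dtype=float)
    libs = libs or [f"L{i}" for i in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                         columns=libs)
    return GeneCountMatrix(raw=frame, normalized=frame)


def _one_factor_design(groups):
    return [SampleMeta(f"L{i}", pop, f"{pop}_f1", "M", "control")
            for i, pop in enumerate(groups)]


class TestCorrelationDistance:
    def test_identical_columns_distance_zero(self):
        m = _matrix([[1, 1], [2, 2], [5, 5]])
        d = correlation_distance(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_distance_two(self):
        m = _matrix([[1, 3], [2, 2], [3, 1]])
        d = correlation_distance(m)
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_invariant_to_library_rescaling(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(40, 6)).astype(float)
        scaled = base * rng.uniform(0.5, 4.0, size=6)
        d1 = correlation_distance(_matrix(base))
        d2 = correlation_distance(_matrix(scaled))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_zero_variance_library_named(self):
        m = _matrix([[1, 1], [2, 1], [3, 1]], libs=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance(m)


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_f(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=14)
        groups = ["lake"] * 7 + ["river"] * 7
        d = np.abs(y[:, None] - y[None, :])
        dist = DistanceMatrix([f"L{i}" for i in range(14)], d)
        table = permanova(dist, _one_factor_design(groups),
                          terms=("population",), n_permutations=99, seed=1)
        f_classic = stats.f_oneway(y[:7], y[7:]).statistic
        assert table["population"].F == pytest.approx(f_classic, abs=1e-10)

    def test_sum_of_squares_partition(self, null_counts, design):
        counts, _ = null_counts
        from sagescape.tag_mapping_counts import normalize_cpm

        dist = correlation_distance(normalize_cpm(counts))
        table = permanova(dist, design, n_permutations=19, seed=0)
        total = sum(r.ss for r in table.rows) + table.ss_residual
        assert total == pytest.approx(table.ss_total, rel=1e-8)
        # Gower identity: total SS = (1/n) sum_{i<j} d_ij^2
        n = len(dist)
        gower = (dist.values[np.triu_indices(n, 1)] ** 2).sum() / n
        assert table.ss_total == pytest.approx(gower, rel=1e-8)

    def test_study_design_degrees_of_freedom(self, null_counts, design):
        """The 24-library design yields the term/residual df of the full
        model (2/17, 1/17, 2/17, 1/17) and the within-treatment models
        (1/3, 2/3, 1/3)."""
        counts, _ = null_counts
        from sagescape.tag_mapping_counts import normalize_cpm

        dist = correlation_distance(normalize_cpm(counts))
        table = permanova(dist, design, n_permutations=19, seed=0)
        assert [(r.df_term, r.df_residual) for r in table.rows] == \
            [(2, 17), (1, 17), (2, 17), (1, 17)]
        control = [s for s in design if s.treatment == "control"]
        libs = [s.library_id for s in control]
        idx = [dist.library_ids.index(l) for l in libs]
        sub = DistanceMatrix(libs, dist.values[np.ix_(idx, idx)])
        within = permanova(sub, control, terms=("population", "family", "sex"),
                           n_permutations=19, seed=0)
        assert [(r.df_term, r.df_residual) for r in within.rows] == \
            [(1, 3), (2, 3), (1, 3)]

    def test_relabeling_libraries_leaves_f_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        groups = ["lake"] * 5 + ["river"] * 5
        design = _one_factor_design(groups)
        dist = DistanceMatrix([s.library_id for s in design], d)
        t1 = permanova(dist, design, terms=("population",),
                       n_permutations=49, seed=2)
        perm = rng.permutation(10)
        dist2 = DistanceMatrix([design[i].library_id for i in perm],
                               d[np.ix_(perm, perm)])
        t2 = permanova(dist2, design, terms=("population",),
                       n_permutations=49, seed=2)
        assert t1["population"].F == pytest.approx(t2["population"].F,
                                                   rel=1e-10)

    def test_confounded_term_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        design = _one_factor_design(["lake"] * 4 + ["river"] * 4)
        dist = DistanceMatrix([s.library_id for s in design], d)
        with pytest.raises(ValueError, match="family"):
            # family has one level per population here -> no extra df
            permanova(dist, design, terms=("population", "family"),
                      n_permutations=9, seed=0)

    def test_null_mean_p_near_half(self):
        rng = np.random.default_rng(7)
        ps = []
        design = _one_factor_design(["lake"] * 4 + ["river"] * 4)
        for _ in range(60):
            x = rng.normal(size=(8, 5))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            dist = DistanceMatrix([s.library_id for s in design], d)
            t = permanova(dist, design, terms=("population",),
                          n_permutations=99, seed=int(rng.integers(2**31)))
            ps.append(t["population"].p_value)
        assert abs(np.mean(ps) - 0.5) < 0.11

    def test_same_seed_identical_p(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(8, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        design = _one_factor_design(["lake"] * 4 + ["river"] * 4)
        dist = DistanceMatrix([s.library_id for s in design], d)
        t1 = permanova(dist, design, terms=("population",),
                       n_permutations=99, seed=42)
        t2 = permanova(dist, design, terms=("population",),
                       n_permutations=99, seed=42)
        assert t1["population"].p_value == t2["population"].p_value


class TestNmds:
    def _euclidean(self, points):
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        return DistanceMatrix([f"L{i}" for i in range(len(points))], d)

    def test_perfect_two_dimensional_embedding(self):
        rng = np.random.default_rng(9)
        dist = self._euclidean(rng.normal(size=(12, 2)))
        result = nmds(dist, dims=2, n_starts=4, seed=0)
        assert result.stress < 1e-3

    def test_stress_decreases_with_dimensions(self):
        rng = np.random.default_rng(10)
        dist = self._euclidean(rng.normal(size=(12, 5)))
        s2 = nmds(dist, dims=2, n_starts=6, seed=1).stress
        s4 = nmds(dist, dims=4, n_starts=6, seed=1).stress
        assert s4 <= s2 + 1e-9

    def test_same_seed_identical_coordinates(self):
        rng = np.random.default_rng(11)
        dist = self._euclidean(rng.normal(size=(10, 4)))
        a = nmds(dist, dims=2, n_starts=3, seed=5)
        b = nmds(dist, dims=2, n_starts=3, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_non_finite_distances_rejected(self):
        rng = np.random.default_rng(12)
        dist = self._euclidean(rng.normal(size=(6, 2)))
        dist.values[0, 1] = dist.values[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            nmds(dist, dims=2)
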