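import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from metaconsensus.diversity import (
    DistanceMatrix,
    age_trend,
    bray_curtis,
    mantel_test,
    normalized_alpha,
    pcoa,
    pearson_concordance,
    permanova,
    procrustes_test,
    richness,
)

from conftest import make_profile


class TestNormalizedAlpha:
    def test_uniform_composition_is_maximally_even(self):
        for s in (2, 5, 40):
            assert normalized_alpha(np.full(s, 1.0 / s)) == pytest.approx(1.0)

    def test_single_taxon_scores_zero(self):
        assert normalized_alpha([0.0, 1.0, 0.0]) == 0.0

    def test_hand_computed_three_taxon_value(self):
        # H = -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397, ln 3 = 1.0986
        assert normalized_alpha([0.5, 0.25, 0.25]) == pytest.approx(0.9464, abs=1e-3)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalized_alpha([0.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=20),
        st.floats(0.01, 100.0),
    )
    def test_invariant_to_rescaling(self, values, scale):
        x = np.array(values)
        assert normalized_alpha(x * scale) == pytest.approx(normalized_alpha(x))


def test_richness_counts_strictly_positive_entries():
    assert richness([0.0, 0.0]) == 0
    assert richness([0.5, 0.5, 0.0]) == 2


class TestAgeTrend:
    def test_noiseless_line_recovers_slope(self):
        ages = np.linspace(50, 100, 30)
        res = age_trend(0.001 * ages, ages)
        assert res.slope == pytest.approx(0.001)
        assert res.p_value < 1e-20

    def test_constant_scores_give_flat_trend(self):
        res = age_trend(np.full(10, 0.7), np.linspace(50, 100, 10))
        assert res.slope == 0.0 and res.p_value == 1.0

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_trend([1.0, 2.0, 3.0], [80.0, 80.0, 80.0])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(42)
        ages = rng.uniform(50, 105, 25)
        pvals = [
            age_trend(rng.normal(size=25), ages).p_value for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBrayCurtis:
    def test_identical_and_disjoint_extremes(self):
        prof = make_profile([[0.5, 0.5, 1.0, 0.0], [0.5, 0.5, 0.0, 1.0]])
        d = bray_curtis(prof)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[2, 3] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        d = bray_curtis(make_profile([[0.7, 0.3], [0.3, 0.7]]))
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(make_profile([[0.5, 0.0], [0.5, 0.0]]))


class TestPCoA:
    def test_collinear_points_load_on_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        d = DistanceMatrix(ids=list("abcd"), values=squareform(pdist(pts)))
        res = pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = DistanceMatrix(
            ids=[str(i) for i in range(12)], values=squareform(pdist(pts))
        )
        res = pcoa(d)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rebuilt, d.values, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        d = DistanceMatrix(ids=list("wxyz"), values=squareform(pdist(pts)))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        assert np.allclose(coords[1], coords[2], atol=1e-8)

    def test_small_matrices_rejected(self):
        d = DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            pcoa(d)

    def test_matches_reference_ordination_variance_fractions(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        prof = make_profile(np.random.default_rng(3).dirichlet(np.ones(8), 10).T)
        d = bray_curtis(prof)
        ours = pcoa(d)
        theirs = skbio_ordination.pcoa(d.values, number_of_dimensions=3)
        ref = theirs.proportion_explained.to_numpy()[:3]
        # same positive-eigenvalue variance fractions up to skbio's total
        scale = ours.proportion_explained[:3] / ref
        assert np.allclose(scale, scale[0], atol=1e-6)


def _scalar_distance_matrix(y):
    y = np.asarray(y, dtype=float)
    return DistanceMatrix(
        ids=[str(i) for i in range(y.size)],
        values=np.abs(y[:, None] - y[None, :]),
    )


class TestPermanova:
    def test_pseudo_f_equals_univariate_regression_f_for_scalar_data(self):
        # Euclidean distances of scalar responses: the distance-based F must
        # equal the classic OLS F = t^2 of y on x
        rng = np.random.default_rng(0)
        y = rng.normal(size=15)
        x = rng.normal(size=15)
        res = permanova(_scalar_distance_matrix(y), x, n_perm=99, seed=1)
        ols_f = stats.linregress(x, y).rvalue**2 * 13 / (1 - stats.linregress(x, y).rvalue**2)
        assert res.statistic == pytest.approx(ols_f, rel=1e-8)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=5)
        x = rng.normal(size=5)
        res = permanova(_scalar_distance_matrix(y), x, exact=True)
        # independent oracle: enumerate OLS F over all covariate orderings
        def ols_f(xp):
            r2 = stats.linregress(xp, y).rvalue ** 2
            return r2 / (1 - r2)
        f_obs = ols_f(x)
        hits = sum(
            ols_f(x[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.p_value == pytest.approx(hits / math.factorial(5))

    def test_separated_clusters_reach_minimum_p(self):
        # covariate perfectly ordered with two separated clusters: no sampled
        # permutation can beat the observed pseudo-F (ties with the exact
        # reversal are possible in principle but have probability ~ 1/12!)
        y = np.concatenate([np.arange(6) * 0.01, 10 + np.arange(6) * 0.01])
        x = np.arange(12, dtype=float)
        res = permanova(_scalar_distance_matrix(y), x, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            y = rng.normal(size=18)
            x = rng.normal(size=18)
            res = permanova(_scalar_distance_matrix(y), x, n_perm=99,
                            seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        se = math.sqrt(0.05 * 0.95 / n_sims)
        assert rejections / n_sims <= 0.05 + 2 * se

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            permanova(_scalar_distance_matrix([1.0, 2.0, 3.0]), [5.0, 5.0, 5.0])


class TestProcrustes:
    def test_similarity_transform_is_perfect_concordance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ rot + np.array([5.0, -2.0])
        from metaconsensus.diversity import OrdinationResult

        ids = [str(i) for i in range(10)]
        oa = OrdinationResult(pd.DataFrame(a, index=ids), np.ones(2), np.ones(2) / 2)
        ob = OrdinationResult(pd.DataFrame(b, index=ids), np.ones(2), np.ones(2) / 2)
        res = procrustes_test(oa, ob, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-8)
        assert res.p_value == pytest.approx(1 / 100)

    def test_exact_p_matches_brute_force_enumeration(self):
        from metaconsensus.diversity import OrdinationResult

        rng = np.random.default_rng(9)
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        ids = list("abcde")
        oa = OrdinationResult(pd.DataFrame(a, index=ids), np.ones(2), np.ones(2) / 2)
        ob = OrdinationResult(pd.DataFrame(b, index=ids), np.ones(2), np.ones(2) / 2)
        res = procrustes_test(oa, ob, exact=True)
        stat = lambda m: math.sqrt(1 - scipy_procrustes(a, m)[2])
        s_obs = stat(b)
        hits = sum(
            stat(b[list(p), :]) >= s_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.p_value == pytest.approx(hits / 120)

    def test_mismatched_samples_rejected(self):
        from metaconsensus.diversity import OrdinationResult

        oa = OrdinationResult(pd.DataFrame(np.eye(3), index=list("abc")),
                              np.ones(3), np.ones(3) / 3)
        ob = OrdinationResult(pd.DataFrame(np.eye(3), index=list("abd")),
                              np.ones(3), np.ones(3) / 3)
        with pytest.raises(ValueError, match="same samples"):
            procrustes_test(oa, ob, n_perm=99, seed=0)


class TestMantel:
    def _random_distance(self, rng, n):
        pts = rng.normal(size=(n, 3))
        return DistanceMatrix(ids=[str(i) for i in range(n)],
                              values=squareform(pdist(pts)))

    def test_self_and_affine_correlation_is_one(self):
        rng = np.random.default_rng(4)
        d1 = self._random_distance(rng, 8)
        d2 = DistanceMatrix(ids=d1.ids, values=2.0 * d1.values)
        assert mantel_test(d1, d1, n_perm=99, seed=0).statistic == pytest.approx(1.0)
        assert mantel_test(d1, d2, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_statistic_matches_reference_implementation(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        d1 = self._random_distance(rng, 10)
        d2 = self._random_distance(rng, 10)
        ours = mantel_test(d1, d2, n_perm=99, seed=0)
        theirs, _, _ = skbio_distance.mantel(
            d1.values, d2.values, method="pearson", permutations=0
        )
        assert ours.statistic == pytest.approx(float(theirs), abs=1e-10)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        d1 = self._random_distance(rng, 5)
        d2 = self._random_distance(rng, 5)
        res = mantel_test(d1, d2, exact=True)
        v2 = squareform(d2.values, checks=False)
        r_obs = np.corrcoef(squareform(d1.values, checks=False), v2)[0, 1]
        hits = 0
        for p in itertools.permutations(range(5)):
            idx = list(p)
            r = np.corrcoef(
                squareform(d1.values[np.ix_(idx, idx)], checks=False), v2
            )[0, 1]
            hits += r >= r_obs - 1e-12
        assert res.p_value == pytest.approx(hits / 120)

    def test_constant_distances_rejected(self):
        n = 4
        vals = np.ones((n, n)) - np.eye(n)
        d = DistanceMatrix(ids=list("abcd"), values=vals)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, d, n_perm=99, seed=0)


def test_permutation_pvalues_are_deterministic_under_seed():
    rng = np.random.default_rng(10)
    y = rng.normal(size=12)
    x = rng.normal(size=12)
    d = _scalar_distance_matrix(y)
    p1 = permanova(d, x, n_perm=199, seed=123).p_value
    p2 = permanova(d, x, n_perm=199, seed=123).p_value
    assert p1 == p2


def test_pearson_concordance_reports_scipy_values():
    rng = np.random.default_rng(12)
    x = rng.normal(size=30)
    y = x + rng.normal(scale=0.5, size=30)
    res = pearson_concordance(x, y)
    r, p = stats.pearsonr(x, y)
    assert res.statistic == pytest.approx(r) and res.p_value == pytest.approx(p)
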