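"""Compositional statistics: ALR, paired tests, distances, PERMANOVA, NMDS."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
import scipy.stats

from lungsort import (
    TaxaProfile,
    ValidationError,
    alr_difference_regression,
    alr_table,
    alr_transform,
    cytokine_association,
    distance_matrix,
    nmds,
    paired_wilcoxon_by_taxon,
    permanova,
    signed_rank_test,
)
from lungsort.stats import DistanceMatrix, default_pseudocount


# ---------------------------------------------------------------------------
# ALR
# ---------------------------------------------------------------------------

class TestAlr:
    def test_fixed_reference_hand_values(self):
        prof = TaxaProfile.from_dict({"A": 0.2, "B": 0.3, "R": 0.5})
        out = alr_transform(prof, eps=0.0, reference="R")
        assert out["A"] == pytest.approx(math.log(0.4))
        assert out["B"] == pytest.approx(math.log(0.6))
        assert out["R"] == 0.0

    def test_reference_component_is_zero(self):
        prof = TaxaProfile.from_dict({"A": 0.5, "R": 0.5})
        assert alr_transform(prof, eps=1e-6, reference="R")["R"] == 0.0

    def test_scale_invariance(self):
        counts = pd.Series({"A": 3, "B": 7, "C": 10})
        a = alr_transform(TaxaProfile.from_counts(counts), 1e-6)
        b = alr_transform(TaxaProfile.from_counts(counts * 13), 1e-6)
        pd.testing.assert_series_equal(a, b)

    def test_remainder_policy_definition(self):
        prof = TaxaProfile.from_dict({"A": 0.2, "B": 0.8})
        eps = 0.01
        out = alr_transform(prof, eps=eps)
        assert out["A"] == pytest.approx(math.log((0.2 + eps) / (0.8 + eps)))

    def test_missing_fixed_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            alr_transform(TaxaProfile.from_dict({"A": 1.0}), 1e-6, reference="Z")

    def test_default_pseudocount_is_half_min_nonzero(self):
        profiles = pd.DataFrame({"s1": [0.9, 0.1, 0.0], "s2": [0.5, 0.25, 0.25]})
        assert default_pseudocount(profiles) == pytest.approx(0.05)


# ---------------------------------------------------------------------------
# Signed-rank tests
# ---------------------------------------------------------------------------

def enumerate_signed_rank_p(diffs):
    """Brute-force two-sided p over all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in product([1, -1], repeat=len(d))
    ]
    return sum(1 for w in ws if abs(w - mu) >= abs(w_obs - mu) - 1e-12) / len(ws)


class TestSignedRank:
    def test_all_zero_differences_are_na(self):
        w, p, n = signed_rank_test([0.0, 0.0, 0.0, 0.0])
        assert math.isnan(w) and math.isnan(p) and n == 0

    def test_worked_example_with_ties(self):
        w, p, n = signed_rank_test([1, 2, 3, -1])
        assert w == pytest.approx(8.5)  # |1| ties share rank 1.5
        assert p == pytest.approx(enumerate_signed_rank_p([1, 2, 3, -1]))
        assert n == 4

    @pytest.mark.parametrize(
        "diffs",
        [
            [1.5, -2.0, 3.0, 4.0, -0.5],
            [1, 1, -1, 2, 3, -2],
            [5, 4, 3, 2, 1],
            [-1, -2, -3, 4],
        ],
    )
    def test_exact_null_matches_enumeration(self, diffs):
        _, p, _ = signed_rank_test(diffs)
        assert p == pytest.approx(enumerate_signed_rank_p(diffs))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=12)
        _, p, _ = signed_rank_test(d)
        ref = scipy.stats.wilcoxon(d, method="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.3, 1.0, size=40)
        _, p, _ = signed_rank_test(d)
        ref = scipy.stats.wilcoxon(d, method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_taxon_reordering(self):
        alr_b = pd.DataFrame(
            np.random.default_rng(3).normal(size=(4, 6)),
            index=list("ABCD"), columns=[f"b{i}" for i in range(6)],
        )
        alr_r = pd.DataFrame(
            np.random.default_rng(4).normal(size=(4, 6)),
            index=list("ABCD"), columns=[f"r{i}" for i in range(6)],
        )
        pairs = [(f"b{i}", f"r{i}") for i in range(6)]
        out1 = paired_wilcoxon_by_taxon(alr_b, alr_r, pairs)
        perm = ["C", "A", "D", "B"]
        out2 = paired_wilcoxon_by_taxon(alr_b.loc[perm], alr_r.loc[perm], pairs)
        pd.testing.assert_frame_equal(out1.loc[perm], out2)


# ---------------------------------------------------------------------------
# ALR-difference regression
# ---------------------------------------------------------------------------

class TestAlrRegression:
    @staticmethod
    def _covariates(n, rng):
        return pd.DataFrame(
            {
                "group": np.where(np.arange(n) % 2 == 0, "g1", "g2"),
                "sex": rng.choice(["m", "f"], size=n),
                "age": rng.uniform(35, 70, size=n),
                "pack_years": rng.uniform(0, 40, size=n),
            },
            index=[f"p{i}" for i in range(n)],
        )

    def test_exact_linear_function_recovered(self):
        rng = np.random.default_rng(0)
        cov = self._covariates(30, rng)
        group_effect = 1.7
        y = (
            2.0
            + group_effect * (cov["group"] == "g2").astype(float)
            + 0.05 * cov["age"]
            - 0.02 * cov["pack_years"]
        )
        alr_diff = pd.DataFrame([y.to_numpy()], index=["TaxA"], columns=cov.index)
        out = alr_difference_regression(alr_diff, cov)
        assert out.loc["TaxA", "coef_group"] == pytest.approx(group_effect, abs=1e-10)
        assert out.loc["TaxA", "r2"] == pytest.approx(1.0, abs=1e-10)

    def test_null_cohort_flags_few_taxa(self):
        """Permuted labels: BH q-values flag <=10% of 200 null taxa."""
        rng = np.random.default_rng(1)
        cov = self._covariates(40, rng)
        alr_diff = pd.DataFrame(
            rng.normal(size=(200, 40)),
            index=[f"T{i}" for i in range(200)], columns=cov.index,
        )
        out = alr_difference_regression(alr_diff, cov)
        assert (out["q_group"] < 0.05).mean() <= 0.10
        assert (out["q_group"] >= out["p_group"] - 1e-12).all()

    def test_two_points_single_covariate_fit_perfectly(self):
        cov = pd.DataFrame({"group": ["a", "b"]}, index=["p0", "p1"])
        alr_diff = pd.DataFrame([[1.0, 3.0]], index=["T"], columns=cov.index)
        out = alr_difference_regression(alr_diff, cov)
        assert out.loc["T", "coef_group"] == pytest.approx(2.0)
        assert out.loc["T", "r2"] == pytest.approx(1.0)

    def test_rank_deficient_design_names_aliased_columns(self):
        cov = pd.DataFrame(
            {
                "group": ["a", "b", "a", "b"],
                "age": [1.0, 2.0, 3.0, 4.0],
                "pack_years": [2.0, 4.0, 6.0, 8.0],  # 2 * age
            },
            index=[f"p{i}" for i in range(4)],
        )
        alr_diff = pd.DataFrame([[0, 1, 2, 3.0]], index=["T"], columns=cov.index)
        with pytest.raises(ValidationError, match="aliased"):
            alr_difference_regression(alr_diff, cov)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_profiles_are_zero(self):
        profiles = pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["X", "Y"])
        for metric in ("manhattan", "bray_curtis"):
            dm = distance_matrix(profiles, metric)
            assert dm.data[0, 1] == 0.0

    def test_disjoint_support_extremes(self):
        profiles = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["X", "Y"])
        assert distance_matrix(profiles, "manhattan").data[0, 1] == pytest.approx(2.0)
        assert distance_matrix(profiles, "bray_curtis").data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        profiles = pd.DataFrame({"a": [0.6, 0.4], "b": [0.1, 0.9]}, index=["X", "Y"])
        assert distance_matrix(profiles, "manhattan").data[0, 1] == pytest.approx(1.0)
        assert distance_matrix(profiles, "bray_curtis").data[0, 1] == pytest.approx(0.5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        profiles = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=6).T,
            index=[f"t{i}" for i in range(5)], columns=list("abcdef"),
        )
        dm = distance_matrix(profiles, "manhattan")
        order = ["d", "a", "f", "b", "c", "e"]
        dm2 = distance_matrix(profiles[order], "manhattan")
        pd.testing.assert_frame_equal(dm.frame().loc[order, order], dm2.frame())

    def test_manhattan_triangle_inequality(self):
        rng = np.random.default_rng(7)
        profiles = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=5).T, columns=list("abcde")
        )
        d = distance_matrix(profiles, "manhattan").data
        for i, j, k in product(range(5), repeat=3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_unsupported_metric_rejected(self):
        with pytest.raises(ValidationError):
            distance_matrix(pd.DataFrame({"a": [1.0]}), "euclidean")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _line_dm(points):
    pts = np.asarray(points, float)
    return DistanceMatrix(
        ids=tuple(f"s{i}" for i in range(len(pts))),
        data=np.abs(pts[:, None] - pts[None, :]),
    )


def enumerate_permanova_p(dm, labels):
    """Oracle: full enumeration of the label multiset's distinct arrangements."""
    from lungsort.stats import _multiset_permutations

    labels = np.asarray(labels)
    res_obs = permanova(dm, labels, exact_limit=0, n_permutations=1,
                        rng=np.random.default_rng(0))
    f_obs = res_obs.pseudo_f
    fs = []
    for arrangement in _multiset_permutations(labels):
        r = permanova(dm, arrangement, exact_limit=0, n_permutations=1,
                      rng=np.random.default_rng(0))
        fs.append(r.pseudo_f)
    fs = np.array(fs)
    return float((fs >= f_obs - 1e-9).sum() / fs.size)


class TestPermanova:
    def test_two_cluster_worked_instance(self):
        dm = _line_dm([0, 1, 10, 11])
        res = permanova(dm, ["g1", "g1", "g2", "g2"])
        assert res.ss_total == pytest.approx(101.0)
        assert res.ss_within == pytest.approx(1.0)
        assert res.pseudo_f == pytest.approx(200.0)
        assert res.r2 == pytest.approx(100.0 / 101.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            enumerate_permanova_p(dm, ["g1", "g1", "g2", "g2"])
        )

    def test_identity_arrangement_reproduces_observed_f(self):
        dm = _line_dm([0, 1, 10, 11])
        res = permanova(dm, ["g1", "g1", "g2", "g2"])
        assert np.any(np.isclose(res.permuted_f, res.pseudo_f))

    def test_exact_matches_monte_carlo_within_binomial_error(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=8)
        pts[4:] += 1.0
        dm = _line_dm(pts)
        labels = ["a"] * 4 + ["b"] * 4
        exact = permanova(dm, labels).p_value
        mc = permanova(
            dm, labels, exact_limit=0, n_permutations=10_000,
            rng=np.random.default_rng(99),
        ).p_value
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) <= 3 * se + 2e-4  # +O(1/N) estimator bias

    def test_r2_partition_identity(self):
        rng = np.random.default_rng(13)
        dm = _line_dm(rng.normal(size=10))
        res = permanova(dm, ["a"] * 5 + ["b"] * 5)
        assert res.r2 + res.ss_within / res.ss_total == pytest.approx(1.0, abs=1e-10)

    def test_identical_clouds_are_null(self):
        rng = np.random.default_rng(14)
        cloud = rng.normal(size=20)
        dm = _line_dm(np.concatenate([cloud, cloud]))
        res = permanova(dm, ["a"] * 20 + ["b"] * 20, n_permutations=999,
                        rng=np.random.default_rng(0))
        assert res.r2 < 0.02
        assert res.p_value > 0.5

    def test_singleton_group_rejected(self):
        dm = _line_dm([0, 1, 2])
        with pytest.raises(ValidationError):
            permanova(dm, ["a", "a", "b"])

    def test_matches_scikit_bio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(15)
        profiles = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=12).T,
            columns=[f"s{i}" for i in range(12)],
        )
        dm = distance_matrix(profiles, "manhattan")
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.data, ids=list(dm.ids)),
            grouping=labels,
            permutations=99,
        )
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_covariate_adjustment_sequential(self):
        """A covariate collinear with the effect absorbs it; noise does not."""
        rng = np.random.default_rng(16)
        pts = np.concatenate([rng.normal(0, 1, 10), rng.normal(4, 1, 10)])
        dm = _line_dm(pts)
        labels = ["a"] * 10 + ["b"] * 10
        cov_noise = pd.DataFrame({"age": rng.normal(size=20)}, index=list(dm.ids))
        cov_confound = pd.DataFrame(
            {"age": (np.array([0] * 10 + [1] * 10) + rng.normal(0, 0.01, 20))},
            index=list(dm.ids),
        )
        res_noise = permanova(dm, labels, covariates=cov_noise,
                              n_permutations=99, rng=np.random.default_rng(1))
        res_conf = permanova(dm, labels, covariates=cov_confound,
                             n_permutations=99, rng=np.random.default_rng(1))
        assert res_noise.ss_between > 10 * res_conf.ss_between


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def kruskal_stress(dm, coords):
    """Stress-1 recomputed independently with isotonic regression."""
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(len(coords), k=1)
    d_conf = ssd.squareform(ssd.pdist(coords))[iu]
    d_in = dm.data[iu]
    order = np.argsort(d_in, kind="stable")
    disp = IsotonicRegression().fit_transform(np.arange(len(order)), d_conf[order])
    resid = d_conf[order] - disp
    return math.sqrt((resid**2).sum() / (d_conf**2).sum())


class TestNmds:
    def test_embeddable_configuration_has_near_zero_stress(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(12, 2))
        dm = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(12)),
            data=ssd.squareform(ssd.pdist(pts)),
        )
        res = nmds(dm, restarts=8, seed=0)
        assert res.stress <= 0.01
        assert res.converged

    def test_unit_square_geometry_recovered(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        dm = DistanceMatrix(
            ids=("a", "b", "c", "d"), data=ssd.squareform(ssd.pdist(sq))
        )
        res = nmds(dm, restarts=16, seed=0)
        assert res.stress <= 0.05
        d = ssd.squareform(ssd.pdist(res.coordinates.to_numpy()))
        side = np.mean([d[0, 1], d[1, 2], d[2, 3], d[0, 3]])
        diag = np.mean([d[0, 2], d[1, 3]])
        assert diag / side == pytest.approx(math.sqrt(2), abs=0.15)

    def test_coordinates_are_centred_and_stress_rotation_invariant(self):
        rng = np.random.default_rng(18)
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(10)),
            data=ssd.squareform(ssd.pdist(pts)),
        )
        res = nmds(dm, restarts=4, seed=1)
        coords = res.coordinates.to_numpy()
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        s0 = kruskal_stress(dm, coords)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        s1 = kruskal_stress(dm, coords @ rot)
        assert s1 == pytest.approx(s0, abs=1e-10)
        assert s0 == pytest.approx(res.stress, abs=0.02)

    def test_group_centroids_are_member_means(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(8)),
            data=ssd.squareform(ssd.pdist(pts)),
        )
        groups = ["a"] * 4 + ["b"] * 4
        res = nmds(dm, restarts=4, seed=2, grouping=groups)
        manual = res.coordinates.groupby(pd.Series(groups, index=res.coordinates.index)).mean()
        pd.testing.assert_frame_equal(res.centroids, manual)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(ids=("a", "b"), data=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            nmds(dm, n_components=2)


# ---------------------------------------------------------------------------
# Cytokine association
# ---------------------------------------------------------------------------

class TestCytokineAssociation:
    def test_identity_coupling(self):
        load = np.array([10.0, 100.0, 1000.0, 5000.0])
        reg = cytokine_association(load, load)
        assert reg.slope == pytest.approx(1.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_shuffled_pairs_are_uncorrelated(self):
        rng = np.random.default_rng(20)
        load = np.exp(rng.normal(10, 1.5, size=42))
        cyt = np.exp(-2 + 0.5 * np.log(load))
        reg = cytokine_association(load, rng.permutation(cyt))
        assert reg.r2 < 0.1

    def test_zero_values_are_half_minimum_shifted(self):
        load = np.array([10.0, 100.0, 1000.0])
        cyt = np.array([0.0, 5.0, 50.0])
        reg = cytokine_association(load, cyt)
        assert np.isfinite(reg.slope)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            cytokine_association([1.0, 2.0], [1.0, 2.0])
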