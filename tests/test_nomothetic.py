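"""Cohort aggregation, Distatis, outcome classification, and density tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symdyn.catalog import ITEM_IDS
from symdyn.idiographic import DistanceMatrix, ward_cluster
from symdyn.nomothetic import (
    classify_outcomes,
    congruence_coefficient,
    cronbach_alpha,
    density_comparison,
    distatis,
    item_trajectory_model,
    rank_sum_test,
    scree_and_elbow,
    weighted_mean_matrix,
)
from symdyn.series import PatientSeries


def full_matrix(values, patient_id=None):
    return DistanceMatrix(ITEM_IDS, values, patient_id)


def random_full_matrix(rng, scale=1.0):
    A = rng.uniform(0.5, 3.0, (17, 17)) * scale
    D = np.triu(A, 1)
    return full_matrix(D + D.T)


# ---------------------------------------------------------------------------
# Weighted cohort matrix
# ---------------------------------------------------------------------------

class TestWeightedMean:
    def test_assessment_weighted_average(self):
        d1 = np.zeros((17, 17)); d1[0, 1] = d1[1, 0] = 2.0
        d2 = np.zeros((17, 17)); d2[0, 1] = d2[1, 0] = 5.0
        cohort = weighted_mean_matrix([full_matrix(d1), full_matrix(d2)], [4, 2])
        assert cohort.values[0, 1] == pytest.approx((2 * 4 + 5 * 2) / 6)

    def test_equal_weights_reduce_to_plain_mean(self, rng):
        mats = [random_full_matrix(rng) for _ in range(3)]
        cohort = weighted_mean_matrix(mats, [2, 2, 2])
        assert np.allclose(cohort.values, np.mean([m.values for m in mats], axis=0))

    def test_single_patient_identity(self, rng):
        m = random_full_matrix(rng)
        cohort = weighted_mean_matrix([m], [5])
        assert np.allclose(cohort.values, m.values)
        assert cohort.support[0, 1] == 1

    def test_unsupported_pair_is_missing_and_blocks_clustering(self, rng):
        m = random_full_matrix(rng)
        reduced = m.subset(tuple(i for i in ITEM_IDS if i != 17))
        cohort = weighted_mean_matrix([reduced], [3])
        assert np.isnan(cohort.values[0, 16])
        assert cohort.support[0, 16] == 0
        with pytest.raises(ValueError, match="zero patients"):
            cohort.distance_matrix()

    def test_mean_within_per_patient_range(self, rng):
        mats = [random_full_matrix(rng) for _ in range(4)]
        cohort = weighted_mean_matrix(mats, [2, 3, 4, 5])
        stack = np.stack([m.values for m in mats])
        assert np.all(cohort.values >= stack.min(axis=0) - 1e-12)
        assert np.all(cohort.values <= stack.max(axis=0) + 1e-12)


# ---------------------------------------------------------------------------
# Scree / elbow
# ---------------------------------------------------------------------------

class _FakeTree:
    def __init__(self, heights_desc):
        # heights_desc: H_1, H_2, ... -> merge heights in ascending order
        self._heights = np.array(heights_desc[::-1], float)
        self.n_leaves = len(self._heights) + 1

    @property
    def heights(self):
        return self._heights


class TestScreeAndElbow:
    def test_maximum_curvature_example(self):
        tree = _FakeTree([10, 7, 3, 2.8, 2.6, 2.5])
        H, k_star = scree_and_elbow(tree, k_max=6)
        assert list(H) == [10, 7, 3, 2.8, 2.6, 2.5]
        assert k_star == 3

    def test_linear_heights_tie_picks_smallest_with_warning(self):
        tree = _FakeTree([12, 10, 8, 6, 4, 2, 0.5])
        with pytest.warns(UserWarning, match="tie"):
            _, k_star = scree_and_elbow(tree, k_max=6)
        assert k_star == 2

    def test_too_few_merges_returns_none(self):
        tree = _FakeTree([3, 1])
        H, k_star = scree_and_elbow(tree, k_max=2)
        assert k_star is None


# ---------------------------------------------------------------------------
# Distatis
# ---------------------------------------------------------------------------

class TestDistatis:
    def test_two_point_double_centering(self):
        res = distatis([np.array([[0.0, 2.0], [2.0, 0.0]])])
        S = res.crossproducts[0]
        assert np.allclose(S, [[0.5, -0.5], [-0.5, 0.5]])
        assert res.alpha == pytest.approx([1.0])

    def test_identical_inputs_weighted_uniformly(self, rng):
        D = random_full_matrix(rng).values
        res = distatis([D, D, D])
        assert res.alpha == pytest.approx([1 / 3] * 3)
        assert np.allclose(res.rv, 1.0)
        assert np.allclose(res.compromise, res.crossproducts[0])

    def test_rv_diagonal_is_one(self, rng):
        res = distatis([random_full_matrix(rng).values for _ in range(4)])
        assert np.diag(res.rv) == pytest.approx(np.ones(4))

    def test_proportional_matrices_reduce_to_classical_mds(self, rng):
        # All inputs positive multiples of one matrix: the compromise must
        # reproduce classical MDS (PCoA) of that matrix up to column scale
        # and sign.  scikit-bio's pcoa is the independent reference.
        from skbio.stats.ordination import pcoa

        D = random_full_matrix(rng).values
        res = distatis([c * D for c in (1.0, 2.5, 0.3)], square_distances=True)
        ref = pcoa(D, number_of_dimensions=3).samples.to_numpy()
        for k in range(3):
            r = np.corrcoef(res.factor_scores[:, k], ref[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_eigenvalues_sorted_and_projection_nonnegative(self, rng):
        # DTW dissimilarities are generally non-Euclidean: negative trailing
        # eigenvalues are reported but never enter the factor scores.
        res = distatis([random_full_matrix(rng).values for _ in range(3)])
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.factor_scores.shape[1] == np.sum(res.eigenvalues > 1e-10)
        assert np.all(res.eigenvalues[: res.factor_scores.shape[1]] > 0)

    def test_zero_variance_matrix_excluded(self, rng):
        D = random_full_matrix(rng).values
        with pytest.warns(UserWarning, match="zero total variance"):
            res = distatis([D, np.zeros((17, 17))])
        assert res.kept_matrices == (0,)

    def test_alpha_weights_sum_to_one_and_nonnegative(self, rng):
        res = distatis([random_full_matrix(rng, s).values for s in (1, 2, 3, 4)])
        assert res.alpha.sum() == pytest.approx(1.0)
        assert np.all(res.alpha > 0)


class TestCongruence:
    def test_identical_and_negated_configurations(self, rng):
        F = rng.normal(size=(17, 2))
        assert congruence_coefficient(F, F) == pytest.approx(1.0)
        assert congruence_coefficient(F, -F) == pytest.approx(-1.0)

    def test_orthogonal_configurations(self):
        F1 = np.array([[1.0], [0.0], [1.0], [0.0]])
        F2 = np.array([[0.0], [1.0], [0.0], [-1.0]])
        assert congruence_coefficient(F1, F2) == pytest.approx(0.0)

    def test_zero_norm_undefined(self):
        with pytest.raises(ValueError, match="zero-norm"):
            congruence_coefficient(np.zeros((3, 2)), np.ones((3, 2)))


# ---------------------------------------------------------------------------
# Outcomes and density
# ---------------------------------------------------------------------------

def patient_with_sums(baseline, last, patient_id="P001"):
    """Two-visit patient whose sum scores are exactly baseline and last."""
    def row(total):
        scores = np.zeros(17, dtype=int)
        caps = [4 if i in (1, 2, 3, 7, 8, 9, 10, 11, 15) else 2 for i in ITEM_IDS]
        for j, cap in enumerate(caps):
            take = min(cap, total)
            scores[j] = take
            total -= take
        assert total == 0
        return scores

    return PatientSeries(patient_id, np.stack([row(baseline), row(last)]))


class TestClassifyOutcomes:
    @pytest.mark.parametrize(
        "baseline,last,responder,remitter",
        [
            (20, 10, True, False),   # exactly 50% reduction
            (20, 11, False, False),  # just above the response threshold
            (20, 7, True, True),     # remission cut-off inclusive
            (14, 8, False, False),
            (16, 8, True, False),
        ],
    )
    def test_thresholds(self, baseline, last, responder, remitter):
        r, m = classify_outcomes(patient_with_sums(baseline, last))
        assert (r, m) == (responder, remitter)

    def test_zero_baseline_flagged_undefined(self):
        r, m = classify_outcomes(patient_with_sums(0, 0))
        assert r is None and m is True


class TestRankSum:
    def test_exact_small_sample(self):
        # U = 0 for fully separated groups of 3; exact two-sided p = 2/20.
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)


class TestDensityComparison:
    def test_residuals_centered_and_orthogonal_to_covariates(self, small_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dc = density_comparison(small_cohort.patients)
        t = dc.table
        assert t["residual"].sum() == pytest.approx(0.0, abs=1e-8)
        for cov in ("n_assessments", "baseline_sum"):
            assert np.dot(t["residual"], t[cov]) == pytest.approx(0.0, abs=1e-6)

    def test_no_adjustment_gives_centered_means(self, small_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dc = density_comparison(small_cohort.patients, adjust=False)
        t = dc.table
        assert np.allclose(t["residual"], t["mean_distance"] - t["mean_distance"].mean())

    def test_responders_have_denser_networks_at_default_gain(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dc = density_comparison(default_cohort.patients)
        t = dc.table
        assert t.loc[t.responder == True, "residual"].median() < \
            t.loc[t.responder == False, "residual"].median()  # noqa: E712
        assert dc.tests["response"][1] < 0.05
        assert dc.tests["remission"][1] < 0.05

    def test_permutation_null_p_values_uniform(self, small_cohort):
        # With outcome labels shuffled, the rank test must be calibrated:
        # p-values approximately uniform on [0, 1].
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dc = density_comparison(small_cohort.patients)
        resid = dc.table["residual"].to_numpy()
        n_resp = int((dc.table["responder"] == True).sum())  # noqa: E712
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(1000):
            perm = rng.permutation(len(resid))
            pvals.append(rank_sum_test(resid[perm[:n_resp]], resid[perm[n_resp:]])[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        assert 0.02 <= np.mean(np.array(pvals) < 0.05) <= 0.09


# ---------------------------------------------------------------------------
# Trajectory mixed models
# ---------------------------------------------------------------------------

class TestTrajectoryModel:
    def _patients_linear(self, intercepts, slope, T=5, item=1):
        patients = []
        for i, b in enumerate(intercepts):
            scores = np.zeros((T, 17), dtype=int)
            t = np.arange(T)
            scores[:, item - 1] = np.clip(np.round(b + slope * t), 0, 4).astype(int)
            patients.append(PatientSeries(f"P{i:03d}", scores))
        return patients

    def test_noise_free_common_line(self):
        patients = self._patients_linear([4.0] * 6, -1.0)
        m = item_trajectory_model(patients, 1)
        assert m.intercept == pytest.approx(4.0, abs=1e-6)
        assert m.slope == pytest.approx(-1.0, abs=1e-6)

    def test_constant_item_flagged(self):
        patients = self._patients_linear([2.0] * 4, 0.0)
        m = item_trajectory_model(patients, 1)
        assert m.slope == 0.0
        assert m.flag == "zero variance"

    def test_narrow_item_rescaled_to_common_scale(self):
        # item 4 has range 0-2; constant score 1 must report intercept 2.
        patients = []
        for i in range(4):
            scores = np.zeros((4, 17), dtype=int)
            scores[:, 3] = 1
            patients.append(PatientSeries(f"P{i}", scores))
        m = item_trajectory_model(patients, 4)
        assert m.rescaled
        assert m.intercept == pytest.approx(2.0)

    def test_recovers_random_intercept_slope(self, rng):
        slope = -0.3
        patients = []
        for i in range(100):
            T = int(rng.integers(3, 9))
            b = 2.5 + rng.normal(0, 0.5)
            y = np.clip(np.round(b + slope * np.arange(T) + rng.normal(0, 0.3, T)), 0, 4)
            scores = np.zeros((T, 17), dtype=int)
            scores[:, 0] = y.astype(int)
            patients.append(PatientSeries(f"P{i:03d}", scores))
        m = item_trajectory_model(patients, 1)
        assert m.slope == pytest.approx(slope, abs=0.08)
        assert m.random_intercept_var > 0


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------

class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(1, 7, dtype=float)
        X = np.column_stack([x, x, x])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_hand_computed_three_item_table(self):
        X = np.array([[1, 2, 1], [2, 1, 3], [3, 3, 2], [4, 2, 4]], float)
        # item variances 5/3, 2/3, 5/3; total variance 20/3
        # alpha = 3/2 * (1 - 4 / (20/3)) = 0.6
        assert cronbach_alpha(X) == pytest.approx(0.6)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ValueError, match="alpha undefined"):
            cronbach_alpha(np.ones((4, 3)))


# ---------------------------------------------------------------------------
# Cohort-level exclusion robustness (zero-item sensitivity)
# ---------------------------------------------------------------------------

def test_exclusion_changes_support_never_shared_distances(small_cohort):
    from symdyn.idiographic import patient_distance_matrix

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in small_cohort.patients[:20]:
            full = patient_distance_matrix(p, exclude_all_zero=False)
            excl = patient_distance_matrix(p, exclude_all_zero=True)
            sub = full.subset(excl.items)
            assert np.allclose(sub.values, excl.values)
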