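"""Cohort-level (nomothetic) analysis.

Aggregates per-patient DTW distance matrices into a weighted cohort matrix,
selects the number of dynamic symptom clusters with a scree/elbow rule,
corroborates the clustering with a Distatis compromise analysis, fits
per-item trajectory mixed models, and compares network density (average
DTW distance) between treatment responders/remitters and the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ITEM_IDS, LABEL, MAX_SCORE
from .dtw import DTWParams
from .idiographic import ClusterTree, DistanceMatrix, patient_distance_matrix
from .series import PatientSeries

__all__ = [
    "CohortDistance",
    "DistatisResult",
    "DensityComparison",
    "TrajectoryModel",
    "weighted_mean_matrix",
    "cohort_distance_matrix",
    "scree_and_elbow",
    "distatis",
    "congruence_coefficient",
    "classify_outcomes",
    "rank_sum_test",
    "signed_rank_test",
    "density_comparison",
    "item_trajectory_model",
    "cronbach_alpha",
]


# ---------------------------------------------------------------------------
# Weighted cohort distance matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDistance:
    """Weighted mean distance matrix over the cohort.

    Each patient's matrix is weighted by their number of assessments T_p.
    ``support`` counts the patients contributing to each pair (pairs can be
    missing for some patients when identically-zero symptoms are excluded).
    Entries supported by no patient are NaN.
    """

    items: tuple[int, ...]
    values: np.ndarray
    support: np.ndarray
    total_weight: float

    def distance_matrix(self) -> DistanceMatrix:
        """The mean matrix as a DistanceMatrix (errors on missing pairs)."""
        off = ~np.eye(len(self.items), dtype=bool)
        if np.isnan(self.values[off]).any():
            raise ValueError(
                "cohort matrix has pairs supported by zero patients; "
                "cannot cluster an incomplete matrix"
            )
        return DistanceMatrix(self.items, self.values)

    def to_dataframe(self) -> pd.DataFrame:
        labels = [LABEL[i] for i in self.items]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def weighted_mean_matrix(
    matrices: list[DistanceMatrix], weights: list[float]
) -> CohortDistance:
    """Average per-patient distance matrices, weighted per patient.

    D_bar_ij = sum_p w_p d_ij^(p) / sum_p w_p over the patients whose matrix
    includes pair (i, j); the spec'd weights are the numbers of assessments.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    if len(matrices) != len(weights):
        raise ValueError("one weight per matrix required")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    items = ITEM_IDS
    n = len(items)
    idx = {item: i for i, item in enumerate(items)}
    acc = np.zeros((n, n))
    wsum = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    for D, w in zip(matrices, weights):
        pos = [idx[i] for i in D.items]
        sel = np.ix_(pos, pos)
        acc[sel] += w * D.values
        wsum[sel] += w
        support[sel] += 1
    with np.errstate(invalid="ignore"):
        values = acc / wsum
    values[wsum == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(support, len(matrices))
    return CohortDistance(items, values, support, float(sum(weights)))


def cohort_distance_matrix(
    patients: list[PatientSeries],
    params: DTWParams = DTWParams(),
    exclude_all_zero: bool = True,
) -> CohortDistance:
    """Convenience: per-patient DTW matrices -> weighted cohort matrix."""
    matrices = [
        patient_distance_matrix(p, params, exclude_all_zero) for p in patients
    ]
    weights = [p.n_assessments for p in patients]
    return weighted_mean_matrix(matrices, weights)


# ---------------------------------------------------------------------------
# Scree / elbow
# ---------------------------------------------------------------------------

def scree_and_elbow(tree: ClusterTree, k_max: int = 8) -> tuple[np.ndarray, int | None]:
    """Scree heights and the automated elbow choice of cluster count.

    H_k is the height of the merge reducing k+1 clusters to k (decreasing in
    k).  The elbow is the point where the downward curve levels off,
    automated as the maximum discrete curvature
    c(k) = (H_{k-1} - H_k) - (H_k - H_{k+1}) over 2 <= k <= k_max - 1; a
    manual override is authoritative when the caller provides one.

    Returns (H[1..k_max] as an array with H[0] = H_1, k_star or None).
    """
    n = tree.n_leaves
    if k_max > n - 1:
        k_max = n - 1
    heights = tree.heights  # ascending merge order; merge m leaves n - m clusters
    H = np.array([heights[n - k - 1] for k in range(1, k_max + 1)])
    if len(H) < 4:
        return H, None
    candidates = range(2, k_max)
    curv = {k: (H[k - 2] - H[k - 1]) - (H[k - 1] - H[k]) for k in candidates}
    best = max(curv.values())
    ties = [k for k in candidates if np.isclose(curv[k], best)]
    if len(ties) > 1:
        warnings.warn(
            f"elbow curvature tie among k={ties}; choosing the smallest",
            UserWarning,
            stacklevel=2,
        )
    return H, ties[0]


# ---------------------------------------------------------------------------
# Distatis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistatisResult:
    """Three-way MDS compromise of a set of conformable distance matrices.

    ``crossproducts`` are the double-centered, first-eigenvalue-normalized
    matrices S_p; ``rv`` the K x K matrix of RV coefficients; ``alpha`` the
    compromise weights (non-negative, summing to 1); ``compromise`` the
    weighted sum S+ = sum alpha_p S_p; ``eigenvalues`` its full spectrum in
    non-increasing order (trailing negatives from non-Euclidean
    dissimilarities are reported but never projected); ``factor_scores`` the
    item coordinates F = V sqrt(lambda) on the retained non-negative
    components.
    """

    items: tuple[int, ...]
    crossproducts: np.ndarray
    rv: np.ndarray
    alpha: np.ndarray
    compromise: np.ndarray
    eigenvalues: np.ndarray
    factor_scores: np.ndarray
    kept_matrices: tuple[int, ...] = field(default=())

    def factor_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": list(self.items),
                "label": [LABEL[i] for i in self.items],
                "F1": self.factor_scores[:, 0],
                "F2": self.factor_scores[:, 1],
            }
        )


def _double_center(D: np.ndarray, square_distances: bool) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    M = D ** 2 if square_distances else D
    return -0.5 * (J @ M @ J)


def distatis(matrices, square_distances: bool = False) -> DistatisResult:
    """Distatis: a compromise cross-product structure for K distance matrices.

    For each matrix, S_p = -1/2 J D_p J (double-centering; distances are
    centered as given by default, with ``square_distances`` exposing the
    textbook squared-distance alternative), normalized by its first
    eigenvalue.  Matrices are compared by RV coefficients
    RV_pq = tr(S_p S_q) / sqrt(tr(S_p^2) tr(S_q^2)); the compromise weights
    alpha are the first eigenvector of the RV matrix rescaled to sum 1, and
    the compromise S+ = sum alpha_p S_p is eigendecomposed to place each
    item in the compromise space.
    """
    mats = [m.values if isinstance(m, DistanceMatrix) else np.asarray(m, float) for m in matrices]
    if not mats:
        raise ValueError("need at least one matrix")
    items: tuple[int, ...]
    first = matrices[0]
    if isinstance(first, DistanceMatrix):
        items = first.items
        if any(isinstance(m, DistanceMatrix) and m.items != items for m in matrices):
            raise ValueError("all matrices must share the same item set")
    else:
        items = tuple(range(1, mats[0].shape[0] + 1))
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all matrices must be conformable")

    S_list, kept = [], []
    for p, D in enumerate(mats):
        S = _double_center(D, square_distances)
        lam1 = float(np.linalg.eigvalsh(S)[-1])
        if lam1 <= 1e-12:
            warnings.warn(
                f"matrix {p} has zero total variance; excluded from Distatis",
                UserWarning,
                stacklevel=2,
            )
            continue
        S_list.append(S / lam1)
        kept.append(p)
    if not S_list:
        raise ValueError("no matrix with positive variance")
    S_arr = np.stack(S_list)
    K = len(S_list)

    inner = np.einsum("pij,qij->pq", S_arr, S_arr)
    norms = np.sqrt(np.diag(inner))
    rv = inner / np.outer(norms, norms)

    if K == 1:
        alpha = np.array([1.0])
    else:
        evals, evecs = np.linalg.eigh(rv)
        v = evecs[:, -1]
        if np.sum(v > 0) < np.sum(v < 0):  # flip so the majority is positive
            v = -v
        alpha = v / v.sum()

    compromise = np.einsum("p,pij->ij", alpha, S_arr)
    compromise = 0.5 * (compromise + compromise.T)
    evals, evecs = np.linalg.eigh(compromise)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-10  # only non-negative components are projected
    F = evecs[:, keep] * np.sqrt(evals[keep])

    return DistatisResult(
        items=items,
        crossproducts=S_arr,
        rv=rv,
        alpha=alpha,
        compromise=compromise,
        eigenvalues=evals,
        factor_scores=F,
        kept_matrices=tuple(kept),
    )


def congruence_coefficient(F1: np.ndarray, F2: np.ndarray) -> float:
    """Tucker's congruence phi = sum(F1*F2) / sqrt(sum F1^2 * sum F2^2).

    Used to compare two factor configurations (e.g., split-half Distatis
    solutions); 1 means identical up to a positive scale factor.
    """
    a, b = np.asarray(F1, float), np.asarray(F2, float)
    if a.shape != b.shape:
        raise ValueError("factor blocks must have identical shapes")
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        raise ValueError("congruence undefined for zero-norm configurations")
    return float((a * b).sum() / denom)


# ---------------------------------------------------------------------------
# Outcomes and network-density comparison
# ---------------------------------------------------------------------------

def classify_outcomes(patient: PatientSeries) -> tuple[bool | None, bool]:
    """Treatment response and remission at the last recorded assessment.

    Response: >= 50% reduction of the HRSD-17 sum versus baseline.
    Remission: final sum <= 7.  A zero baseline leaves response undefined
    (returned as None).
    """
    sums = patient.sum_scores
    baseline, last = int(sums[0]), int(sums[-1])
    remitter = last <= 7
    if baseline == 0:
        return None, remitter
    responder = last <= 0.5 * baseline
    return responder, remitter


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test for independent groups.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise.  Returns (U statistic of the first group, p).
    """
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, for genuinely paired samples."""
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DensityComparison:
    """Per-patient network density and its relation to treatment outcome.

    ``table`` has one row per analyzed patient: mean off-diagonal DTW
    distance, the covariate-adjusted residual, and outcome labels.
    ``tests`` maps "response"/"remission" to (U, p) of the rank-sum test on
    the residuals.  Shorter average distances indicate denser, more
    synchronous symptom networks.
    """

    table: pd.DataFrame
    tests: dict[str, tuple[float, float]]
    adjusted: bool
    covariates: tuple[str, ...]


def density_comparison(
    patients: list[PatientSeries],
    params: DTWParams = DTWParams(),
    adjust: bool = True,
    exclude_all_zero: bool = True,
    covariates: tuple[str, ...] = ("n_assessments", "baseline_sum"),
    matrices: list[DistanceMatrix] | None = None,
) -> DensityComparison:
    """Compare average DTW distance between outcome groups.

    Computes each patient's mean pairwise DTW distance (their inverse
    network density), optionally replaces it by the residual of an OLS
    regression on the number of assessments and the baseline HRSD-17 sum
    (a single pooled regression over all patients), and rank-sum-tests
    responders vs non-responders and remitters vs non-remitters.  Toggling
    ``exclude_all_zero`` off or dropping "baseline_sum" from ``covariates``
    reproduces the published sensitivity analyses.

    ``matrices`` may supply precomputed per-patient distance matrices
    (in the same order as ``patients``) to avoid recomputation.
    """
    import statsmodels.api as sm

    rows = []
    for i, p in enumerate(patients):
        if matrices is not None:
            D = matrices[i]
            if exclude_all_zero:
                D = D.subset(p.nonzero_items())
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                D = patient_distance_matrix(p, params, exclude_all_zero)
        if D.n_items < 2:
            continue
        responder, remitter = classify_outcomes(p)
        rows.append(
            {
                "patient_id": p.patient_id,
                "n_assessments": p.n_assessments,
                "baseline_sum": p.baseline_sum,
                "mean_distance": D.off_diagonal_mean(),
                "responder": responder,
                "remitter": remitter,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty or table["responder"].notna().sum() < 4:
        raise ValueError("too few analyzable patients")

    if adjust:
        used = []
        X = []
        for cov in covariates:
            col = table[cov].to_numpy(float)
            if np.ptp(col) == 0:
                warnings.warn(
                    f"covariate {cov!r} is constant; dropped from the regression",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            used.append(cov)
            X.append(col)
        exog = sm.add_constant(np.column_stack(X)) if X else np.ones((len(table), 1))
        fit = sm.OLS(table["mean_distance"].to_numpy(float), exog).fit()
        table["residual"] = fit.resid
        covariates = tuple(used)
    else:
        table["residual"] = table["mean_distance"] - table["mean_distance"].mean()
        covariates = ()

    tests = {}
    for name, col in (("response", "responder"), ("remission", "remitter")):
        mask = table[col].notna()
        yes = table.loc[mask & (table[col] == True), "residual"]  # noqa: E712
        no = table.loc[mask & (table[col] == False), "residual"]  # noqa: E712
        if len(yes) < 2 or len(no) < 2:
            raise ValueError(f"need at least 2 patients per {name} group")
        tests[name] = rank_sum_test(yes.to_numpy(), no.to_numpy())

    return DensityComparison(table, tests, adjust, covariates)


# ---------------------------------------------------------------------------
# Per-item trajectory mixed models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryModel:
    """Fixed effects of a random-intercept model for one item's trajectory.

    ``intercept`` is the baseline level on the common 0-4 scale (0-2 items
    are doubled before fitting) and ``slope`` the average change per 2-week
    interval.
    """

    item_id: int
    intercept: float
    slope: float
    random_intercept_var: float
    residual_var: float
    rescaled: bool
    flag: str | None = None


def item_trajectory_model(patients: list[PatientSeries], item_id: int) -> TrajectoryModel:
    """Linear mixed model (patient random intercept, REML) for one item.

    Time is measured in 2-week intervals; items with a 0-2 range are scaled
    to 0-4 to make intercepts and slopes comparable across items.
    """
    import statsmodels.api as sm

    rescale = MAX_SCORE[item_id] == 2
    y, t, groups = [], [], []
    for p in patients:
        scores = p.scores[:, item_id - 1].astype(float)
        if rescale:
            scores = scores * 2.0
        y.append(scores)
        t.append(p.weeks / 2.0)
        groups.extend([p.patient_id] * p.n_assessments)
    y = np.concatenate(y)
    t = np.concatenate(t)
    if len(set(groups)) < 2:
        raise ValueError("need at least 2 patients")

    if np.ptp(y) == 0:  # constant item: intercept is that constant, slope 0
        return TrajectoryModel(item_id, float(y[0]), 0.0, 0.0, 0.0, rescale,
                               flag="zero variance")

    exog = sm.add_constant(t)
    ols = sm.OLS(y, exog).fit()
    if ols.ssr < 1e-10:  # exact common line: the mixed model is singular
        return TrajectoryModel(item_id, float(ols.params[0]), float(ols.params[1]),
                               0.0, 0.0, rescale, flag="no residual variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=np.asarray(groups))
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            return TrajectoryModel(item_id, float(ols.params[0]), float(ols.params[1]),
                                   0.0, float(ols.mse_resid), rescale,
                                   flag="mixed model singular; pooled OLS")
    return TrajectoryModel(
        item_id=item_id,
        intercept=float(fit.fe_params[0]),
        slope=float(fit.fe_params[1]),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        rescaled=rescale,
    )


def trajectory_table(patients: list[PatientSeries]) -> pd.DataFrame:
    """Fixed-effect intercept and slope for every HRSD-17 item."""
    rows = []
    for item_id in ITEM_IDS:
        m = item_trajectory_model(patients, item_id)
        rows.append(
            {
                "item": item_id,
                "label": LABEL[item_id],
                "intercept": m.intercept,
                "slope": m.slope,
                "rescaled": m.rescaled,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Internal consistency
# ---------------------------------------------------------------------------

def cronbach_alpha(scores: np.ndarray) -> float:
    """Cronbach's alpha of a patients x items score matrix at one visit.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), with unbiased
    (n-1) sample variances.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 patients and 2 items")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))
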