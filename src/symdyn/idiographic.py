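"""Per-patient (idiographic) analysis.

For one patient: the pairwise DTW distance matrix over HRSD-17 item
trajectories, an agglomerative (Ward.D2) cluster tree, and a symptom
network with strength and closeness centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .catalog import ITEM_IDS, LABEL
from .dtw import DTWParams, pairwise_dtw
from .series import PatientSeries

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "SymptomNetwork",
    "patient_distance_matrix",
    "ward_cluster",
    "cut_tree",
    "build_network",
    "patient_report",
]

MIN_ITEMS = 3  # below this, clustering / networks are not meaningful


class DegenerateMatrixWarning(UserWarning):
    """Fewer than MIN_ITEMS included items: clustering/network are skipped."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise DTW distances between item trajectories.

    ``items`` are the included HRSD item ids (columns of ``values`` in the
    same order); the diagonal is zero.
    """

    items: tuple[int, ...]
    values: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match item count")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_pairs(self) -> int:
        return self.n_items * (self.n_items - 1) // 2

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy's condensed order."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]

    def off_diagonal_mean(self) -> float:
        """Mean pairwise distance (the inverse of network density)."""
        if self.n_items < 2:
            raise ValueError("need at least 2 items")
        return float(self.condensed().mean())

    def subset(self, items: tuple[int, ...]) -> "DistanceMatrix":
        idx = [self.items.index(i) for i in items]
        return DistanceMatrix(tuple(items), self.values[np.ix_(idx, idx)], self.patient_id)

    def to_dataframe(self) -> pd.DataFrame:
        labels = [LABEL[i] for i in self.items]
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge sequence over the items of a distance matrix.

    ``merges`` lists (a, b, height) with scipy-style cluster ids: leaves are
    0..n-1 in the order of ``items``, and the cluster created by merge m
    gets id n + m.  Heights are on the original distance scale (square root
    of the Ward criterion) and are non-decreasing.
    """

    items: tuple[int, ...]
    merges: tuple[tuple[int, int, float], ...]
    sizes: tuple[int, ...]  # size of the cluster created by each merge

    @property
    def n_leaves(self) -> int:
        return len(self.items)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_linkage(self) -> np.ndarray:
        """scipy linkage matrix (for dendrograms, cutting, leaf order)."""
        Z = np.zeros((len(self.merges), 4))
        for m, ((a, b, h), size) in enumerate(zip(self.merges, self.sizes)):
            Z[m] = (a, b, h, size)
        return Z

    def leaf_order(self) -> tuple[int, ...]:
        """Item ids in dendrogram leaf order (deterministic heatmap order)."""
        order = sch.leaves_list(self.to_linkage())
        return tuple(self.items[i] for i in order)


@dataclass(frozen=True)
class SymptomNetwork:
    """Complete weighted symptom network derived from a distance matrix.

    Edge weights are similarities in [0, 1]; ``strength`` is the sum of a
    node's edge weights and ``closeness`` the inverse of its mean DTW
    distance to all other symptoms.
    """

    items: tuple[int, ...]
    weights: np.ndarray
    strength: np.ndarray
    closeness: np.ndarray
    similarity: str = "minmax"

    def centrality_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": list(self.items),
                "label": [LABEL[i] for i in self.items],
                "strength": self.strength,
                "closeness": self.closeness,
            }
        )


def patient_distance_matrix(
    patient: PatientSeries,
    params: DTWParams = DTWParams(),
    exclude_all_zero: bool = True,
) -> DistanceMatrix:
    """Pairwise DTW distances between a patient's item trajectories.

    With all 17 items included the matrix holds (17^2 - 17) / 2 = 136
    distinct pairwise distances.  When ``exclude_all_zero`` is set, symptoms
    scoring 0 at every visit are dropped before pairing (such pairs have
    distance 0 merely because the symptoms are absent); dropping them never
    changes the distances among the remaining items.
    """
    full = pairwise_dtw(patient.scores.astype(float), params)
    if params.normalized:
        full = full / (2 * patient.n_assessments)
    items: tuple[int, ...] = ITEM_IDS
    if exclude_all_zero:
        keep = [j for j, item_id in enumerate(ITEM_IDS) if patient.scores[:, j].any()]
        items = tuple(ITEM_IDS[j] for j in keep)
        full = full[np.ix_(keep, keep)]
    if len(items) < MIN_ITEMS:
        warnings.warn(
            f"patient {patient.patient_id}: only {len(items)} item(s) included; "
            "clustering and network statistics are not meaningful",
            DegenerateMatrixWarning,
            stacklevel=2,
        )
    return DistanceMatrix(items, full, patient.patient_id)


def _validate_square(D) -> tuple[tuple[int, ...], np.ndarray]:
    if isinstance(D, DistanceMatrix):
        return D.items, D.values
    values = np.asarray(D, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(values, values.T) or np.any(values < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    return tuple(range(1, values.shape[0] + 1)), values


def ward_cluster(D) -> ClusterTree:
    """Agglomerative Ward.D2 clustering of a distance matrix.

    Dissimilarities are squared before cluster updating; inter-cluster
    criteria follow the Lance-Williams recurrence

        d2(t, k) = [(n_i + n_k) d2(i, k) + (n_j + n_k) d2(j, k)
                    - n_k d2(i, j)] / (n_i + n_j + n_k)

    for the merged cluster t = i u j, and the reported merge height is the
    square root of the criterion (original distance scale).  Ties are broken
    by the lexicographically smallest (min id, max id) cluster pair, which
    makes the tree deterministic across platforms.
    """
    items, values = _validate_square(D)
    n = len(items)
    if n < MIN_ITEMS:
        raise ValueError(f"need at least {MIN_ITEMS} items to cluster")

    crit = values.astype(float) ** 2  # Ward criterion between singletons
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    crit_map: dict[frozenset, float] = {
        frozenset((i, j)): crit[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    sizes: list[int] = []
    next_id = n
    while len(active) > 1:
        best_pair, best_val = None, np.inf
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                v = crit_map[frozenset((a, b))]
                if v < best_val and not np.isclose(v, best_val):
                    best_pair, best_val = (a, b), v
        a, b = best_pair
        na, nb = active[a], active[b]
        nt = na + nb
        merges.append((a, b, float(np.sqrt(best_val))))
        sizes.append(nt)
        del active[a], active[b]
        for k in active:
            nk = active[k]
            dak = crit_map.pop(frozenset((a, k)))
            dbk = crit_map.pop(frozenset((b, k)))
            crit_map[frozenset((next_id, k))] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * best_val
            ) / (nt + nk)
        crit_map.pop(frozenset((a, b)), None)
        active[next_id] = nt
        next_id += 1

    return ClusterTree(items, tuple(merges), tuple(sizes))


def cut_tree(tree: ClusterTree, k: int) -> dict[int, int]:
    """Cut the tree into exactly ``k`` groups (default patient reports use 3).

    Returns item id -> cluster label (1..k); labels are renumbered in order
    of first appearance for determinism.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in 1..{tree.n_leaves}")
    raw = sch.cut_tree(tree.to_linkage(), n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels: dict[int, int] = {}
    for item, lab in zip(tree.items, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[item] = relabel[lab]
    return labels


def build_network(D: DistanceMatrix, similarity: str = "minmax") -> SymptomNetwork:
    """Derive the symptom network and centralities from a distance matrix.

    Edge weights: with ``similarity="minmax"`` (default),
    s_ij = (d_max - d_ij) / (d_max - d_min) over off-diagonal entries, so the
    closest item pair gets weight 1 and the farthest weight 0; with
    ``"inverse"``, s_ij = 1 / d_ij (zero distances capped at the largest
    finite similarity).  Strength_i = sum_j s_ij; closeness_i is the inverse
    of the mean DTW distance from i to all other symptoms.
    """
    items, values = _validate_square(D)
    n = len(items)
    if n < MIN_ITEMS:
        raise ValueError(f"need at least {MIN_ITEMS} items")
    off = ~np.eye(n, dtype=bool)
    d_off = values[off]
    if np.allclose(d_off, d_off[0]):
        warnings.warn(
            "all pairwise distances equal; similarity undefined, using uniform weights",
            UserWarning,
            stacklevel=2,
        )
        weights = np.ones((n, n))
    elif similarity == "minmax":
        d_min, d_max = d_off.min(), d_off.max()
        weights = (d_max - values) / (d_max - d_min)
    elif similarity == "inverse":
        with np.errstate(divide="ignore"):
            weights = 1.0 / values
        finite = weights[off][np.isfinite(weights[off])]
        cap = finite.max() if finite.size else 1.0
        weights[~np.isfinite(weights)] = cap
    else:
        raise ValueError("similarity must be 'minmax' or 'inverse'")
    np.fill_diagonal(weights, 0.0)
    strength = weights.sum(axis=1)
    mean_d = values.sum(axis=1) / (n - 1)
    closeness = 1.0 / mean_d
    return SymptomNetwork(items, weights, strength, closeness, similarity)


def patient_report(
    patient: PatientSeries,
    params: DTWParams = DTWParams(),
    exclude_all_zero: bool = True,
    k: int = 3,
    similarity: str = "minmax",
) -> dict:
    """JSON-serializable per-patient report: distances, clusters, network.

    ``k`` defaults to 3 clusters, an illustrative cut that eases reading of
    individual dendrograms.  Patients with fewer than three included items
    get a report flagged ``"insufficient items"`` instead of an error.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateMatrixWarning)
        D = patient_distance_matrix(patient, params, exclude_all_zero)
    report: dict = {
        "patient_id": patient.patient_id,
        "n_assessments": patient.n_assessments,
        "included_items": list(D.items),
        "distance_matrix": D.values.tolist(),
        "baseline_sum": patient.baseline_sum,
    }
    if D.n_items < MIN_ITEMS:
        report["status"] = "insufficient items"
        return report
    tree = ward_cluster(D)
    network = build_network(D, similarity)
    report.update(
        status="ok",
        merges=[[int(a), int(b), float(h)] for a, b, h in tree.merges],
        labels={str(item): lab for item, lab in cut_tree(tree, min(k, D.n_items)).items()},
        leaf_order=list(tree.leaf_order()),
        strength={str(i): float(s) for i, s in zip(network.items, network.strength)},
        closeness={str(i): float(c) for i, c in zip(network.items, network.closeness)},
    )
    return report
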