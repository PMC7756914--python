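"""End-to-end cohort analysis: everything the CLI's ``cohort`` command writes.

Thin orchestration over the idiographic and nomothetic modules; all design
toggles (band width, zero exclusion, similarity transform, adjustment
covariates, manual k) are surfaced here and recorded in the returned
metadata so runs are fully reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dtw import DTWParams
from .idiographic import build_network, patient_distance_matrix, ward_cluster, cut_tree
from .nomothetic import (
    density_comparison,
    distatis,
    scree_and_elbow,
    trajectory_table,
    weighted_mean_matrix,
)
from .series import PatientSeries

__all__ = ["analyze_cohort", "write_cohort_report"]


def analyze_cohort(
    patients: list[PatientSeries],
    params: DTWParams = DTWParams(),
    exclude_all_zero: bool = True,
    similarity: str = "minmax",
    k: int | None = None,
    k_max: int = 8,
    adjust: bool = True,
    run_distatis: bool = True,
) -> dict:
    """Run the full nomothetic pipeline and return all result objects.

    ``k=None`` uses the automated elbow; an explicit ``k`` is authoritative.
    Distatis always receives full 17-item matrices (computed without the
    all-zero exclusion) so every patient contributes a conformable matrix.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_matrices = [patient_distance_matrix(p, params, exclude_all_zero=False) for p in patients]
    weights = [p.n_assessments for p in patients]
    if exclude_all_zero:
        matrices = [D.subset(p.nonzero_items()) for D, p in zip(full_matrices, patients)]
    else:
        matrices = full_matrices

    cohort = weighted_mean_matrix(matrices, weights)
    D_bar = cohort.distance_matrix()
    tree = ward_cluster(D_bar)
    heights, k_star = scree_and_elbow(tree, k_max=k_max)
    k_used = k if k is not None else (k_star or 3)
    labels = cut_tree(tree, k_used)
    network = build_network(D_bar, similarity)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        density = density_comparison(
            patients,
            params,
            adjust=adjust,
            exclude_all_zero=exclude_all_zero,
            matrices=full_matrices if exclude_all_zero else matrices,
        )
        trajectories = trajectory_table(patients)
        dist = distatis(full_matrices) if run_distatis else None

    return {
        "cohort_distance": cohort,
        "tree": tree,
        "scree_heights": heights,
        "k_star": k_star,
        "k_used": k_used,
        "labels": labels,
        "network": network,
        "distatis": dist,
        "density": density,
        "trajectories": trajectories,
        "settings": {
            "band_width": params.band_width,
            "step_pattern": params.step_pattern,
            "normalized": params.normalized,
            "exclude_all_zero": exclude_all_zero,
            "similarity": similarity,
            "k": k,
            "k_max": k_max,
            "adjust": adjust,
        },
    }


def write_cohort_report(results: dict, outdir: str | Path) -> None:
    """Serialize analyze_cohort results to CSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results["cohort_distance"].to_dataframe().to_csv(outdir / "cohort_distance.csv")

    clusters = {
        "k_star": results["k_star"],
        "k_used": results["k_used"],
        "labels": {str(i): int(l) for i, l in results["labels"].items()},
        "scree_heights": [float(h) for h in results["scree_heights"]],
        "merges": [[int(a), int(b), float(h)] for a, b, h in results["tree"].merges],
        "settings": results["settings"],
    }
    (outdir / "clusters.json").write_text(json.dumps(clusters, indent=2))

    if results["distatis"] is not None:
        results["distatis"].factor_table().to_csv(outdir / "distatis.csv", index=False)
    results["network"].centrality_table().to_csv(outdir / "centrality.csv", index=False)
    results["density"].table.to_csv(outdir / "density.csv", index=False)

    tests = {
        name: {"statistic": stat, "p_value": p}
        for name, (stat, p) in results["density"].tests.items()
    }
    (outdir / "tests.json").write_text(json.dumps(tests, indent=2))

    results["trajectories"].to_csv(outdir / "trajectories.csv", index=False)
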