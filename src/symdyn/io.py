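"""Cohort CSV interchange.

The canonical on-disk format is a long-format CSV with one row per visit:
``patient_id, week, item_1 ... item_17``.  Weeks are non-negative even
integers, unique per patient; scores are integers within each item's
catalog range.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ITEM_IDS, MAX_SCORE
from .series import PatientSeries

__all__ = ["read_cohort", "write_cohort", "COLUMNS"]

logger = logging.getLogger("symdyn")

COLUMNS = ["patient_id", "week"] + [f"item_{i}" for i in ITEM_IDS]


def read_cohort(path: str | Path, strict: bool = True) -> list[PatientSeries]:
    """Read a long-format cohort CSV into validated patient series.

    Visits are sorted by week per patient.  Patients with a single
    assessment are dropped (their trajectories cannot be warped) and the
    exclusion count is logged.  Out-of-range scores raise in strict mode
    and are clipped with a warning otherwise; duplicated (patient, week)
    rows always raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")

    dup = df.duplicated(subset=["patient_id", "week"])
    if dup.any():
        first = df.loc[dup, ["patient_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicated (patient, week) rows, e.g. {first.patient_id} week {first.week}"
        )

    for item_id in ITEM_IDS:
        col = f"item_{item_id}"
        values = df[col]
        bad = (values < 0) | (values > MAX_SCORE[item_id])
        if bad.any():
            row = df.index[bad][0]
            if strict:
                raise ValueError(
                    f"score out of range in column {col}, row {row} "
                    f"(value {values[row]}, allowed 0..{MAX_SCORE[item_id]})"
                )
            logger.warning("clipping %d out-of-range values in %s", int(bad.sum()), col)
            df[col] = values.clip(0, MAX_SCORE[item_id])

    patients: list[PatientSeries] = []
    n_single = 0
    for patient_id, group in df.groupby("patient_id", sort=True):
        group = group.sort_values("week")
        if len(group) < 2:
            n_single += 1
            continue
        scores = group[[f"item_{i}" for i in ITEM_IDS]].to_numpy(dtype=np.int64)
        patients.append(
            PatientSeries(
                patient_id=str(patient_id),
                scores=scores,
                weeks=group["week"].to_numpy(dtype=np.int64),
            )
        )
    if n_single:
        logger.info("dropped %d patient(s) with a single assessment", n_single)
    return patients


def write_cohort(patients: list[PatientSeries], path: str | Path) -> None:
    """Write patient series to the long-format CSV (inverse of read_cohort)."""
    rows = []
    for p in patients:
        for visit in range(p.n_assessments):
            row = {"patient_id": p.patient_id, "week": int(p.weeks[visit])}
            row.update(
                {f"item_{i}": int(p.scores[visit, j]) for j, i in enumerate(ITEM_IDS)}
            )
            rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
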