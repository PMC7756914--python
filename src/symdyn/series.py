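"""Per-patient score containers.

A :class:`PatientSeries` holds one patient's repeated HRSD-17 assessments as
a T x 17 integer matrix, one row per biweekly visit, plus the visit weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import ITEM_IDS, MAX_SCORE, N_ITEMS


@dataclass(frozen=True)
class ScoreSeries:
    """One item's trajectory: integer scores at consecutive biweekly visits."""

    item_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a score series needs at least 2 visits")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PatientSeries:
    """A patient's T x 17 score matrix over biweekly visits.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    scores : ndarray of shape (T, 17)
        Integer item scores; column ``j`` is HRSD item ``j + 1``.
    weeks : ndarray of shape (T,)
        Week number of each visit (0, 2, 4, ...), strictly increasing.
    """

    patient_id: str
    scores: np.ndarray
    weeks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.ndim != 2 or scores.shape[1] != N_ITEMS:
            raise ValueError(f"scores must be T x {N_ITEMS}")
        if scores.shape[0] < 2:
            raise ValueError("a patient needs at least 2 assessments")
        for j, item_id in enumerate(ITEM_IDS):
            col = scores[:, j]
            if col.min() < 0 or col.max() > MAX_SCORE[item_id]:
                raise ValueError(
                    f"item {item_id} scores outside 0..{MAX_SCORE[item_id]} "
                    f"for patient {self.patient_id}"
                )
        if self.weeks is None:
            weeks = 2 * np.arange(scores.shape[0], dtype=np.int64)
        else:
            weeks = np.asarray(self.weeks, dtype=np.int64)
            if weeks.shape != (scores.shape[0],):
                raise ValueError("weeks must have one entry per visit")
            if np.any(np.diff(weeks) <= 0):
                raise ValueError("weeks must be strictly increasing")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "weeks", weeks)

    @property
    def n_assessments(self) -> int:
        return self.scores.shape[0]

    @property
    def sum_scores(self) -> np.ndarray:
        """Per-visit HRSD-17 totals (0-52)."""
        return self.scores.sum(axis=1)

    @property
    def baseline_sum(self) -> int:
        return int(self.sum_scores[0])

    def item_series(self, item_id: int) -> ScoreSeries:
        """The trajectory of a single item."""
        return ScoreSeries(item_id, self.scores[:, item_id - 1].astype(float))

    def nonzero_items(self) -> tuple[int, ...]:
        """Items that score non-zero at least once during follow-up."""
        return tuple(
            item_id
            for j, item_id in enumerate(ITEM_IDS)
            if np.any(self.scores[:, j] != 0)
        )
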