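"""The 17-item Hamilton Rating Scale for Depression (HRSD-17) item catalog.

Nine items are rated on a 0-4 Likert scale and eight on a 0-2 scale, so the
sum score ranges from 0 to 52.  Item ids follow the conventional HRSD-17
numbering.  The five dynamic symptom clusters used as the planted ground
truth by the synthetic-cohort generator group items by the similarity of
their course trajectories during inpatient treatment: core symptoms, sleep
(insomnia) symptoms, distress, somatic symptoms, and a broad "inner turmoil"
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Item:
    """One HRSD-17 item: id (1-17), short label, and maximum score (2 or 4)."""

    item_id: int
    label: str
    max_score: int


ITEMS: tuple[Item, ...] = (
    Item(1, "depressed_mood", 4),
    Item(2, "guilt", 4),
    Item(3, "suicide", 4),
    Item(4, "early_insomnia", 2),
    Item(5, "middle_insomnia", 2),
    Item(6, "late_insomnia", 2),
    Item(7, "work_and_interests", 4),
    Item(8, "retardation", 4),
    Item(9, "agitation", 4),
    Item(10, "psychic_anxiety", 4),
    Item(11, "somatic_anxiety", 4),
    Item(12, "gastrointestinal", 2),
    Item(13, "general_somatic", 2),
    Item(14, "genital", 2),
    Item(15, "hypochondriasis", 4),
    Item(16, "weight_loss", 2),
    Item(17, "insight", 2),
)

N_ITEMS = len(ITEMS)

ITEM_IDS: tuple[int, ...] = tuple(item.item_id for item in ITEMS)

#: item_id -> maximum score (minimum is always 0)
MAX_SCORE: dict[int, int] = {item.item_id: item.max_score for item in ITEMS}

#: item_id -> short label
LABEL: dict[int, str] = {item.item_id: item.label for item in ITEMS}

#: Maximum possible HRSD-17 sum score (9 * 4 + 8 * 2 = 52).
MAX_SUM_SCORE = sum(item.max_score for item in ITEMS)

#: Five dynamic symptom clusters (trajectory-similarity groups).
CLUSTER_MAP: dict[str, tuple[int, ...]] = {
    "core": (1, 7),
    "sleep": (4, 5, 6),
    "distress": (2, 10),
    "somatic": (13, 14),
    "inner_turmoil": (3, 8, 9, 11, 12, 15, 16, 17),
}

#: item_id -> cluster name, derived from CLUSTER_MAP.
ITEM_CLUSTER: dict[int, str] = {
    item_id: name for name, members in CLUSTER_MAP.items() for item_id in members
}


def n_pairs(n_items: int) -> int:
    """Number of unordered item pairs, (n^2 - n) / 2 (136 for all 17 items)."""
    return n_items * (n_items - 1) // 2
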