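"""Scoring of the three symptom instruments from item-level responses.

Instruments:

* ADHD-RS — 18 parent-rated items (0-3); odd items form the inattention
  subscale and even items the hyperactivity subscale in the published
  alternation; subscale sums and their total are reported.
* ARI — 7 irritability items (0-2); the conventional symptom total sums
  the first 6 items, the 7th (impairment) being excluded by default.
* RPQ — 23 aggression items (0-2) split into 11 reactive and 12
  proactive items per the published instrument.

Subscale maps are data, not code: each scorer accepts an override so
users can apply a different assignment without modification.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Instrument",
    "Informant",
    "ItemResponses",
    "ScoreSet",
    "ScaleError",
    "INSTRUMENT_SPECS",
    "MEASURES",
    "score_adhd_rs",
    "score_ari",
    "score_rpq",
    "score_subject",
    "scores_to_frame",
    "descriptives",
    "read_item_responses",
    "write_item_responses",
]


class Instrument(str, Enum):
    ADHD_RS = "ADHD_RS"
    ARI = "ARI"
    RPQ = "RPQ"


class Informant(str, Enum):
    PARENT = "parent"
    PARTICIPANT = "participant"


#: instrument -> (number of items, maximum per-item response)
INSTRUMENT_SPECS: dict[Instrument, tuple[int, int]] = {
    Instrument.ADHD_RS: (18, 3),
    Instrument.ARI: (7, 2),
    Instrument.RPQ: (23, 2),
}

# 1-based item positions per the published instruments
ADHD_INATTENTION_ITEMS: tuple[int, ...] = tuple(range(1, 19, 2))
ADHD_HYPERACTIVITY_ITEMS: tuple[int, ...] = tuple(range(2, 19, 2))
RPQ_REACTIVE_ITEMS: tuple[int, ...] = (1, 3, 5, 7, 8, 11, 13, 14, 16, 19, 22)
RPQ_PROACTIVE_ITEMS: tuple[int, ...] = tuple(
    i for i in range(1, 24) if i not in RPQ_REACTIVE_ITEMS
)


class ScaleError(ValueError):
    """Raised for malformed item responses."""


@dataclass(frozen=True)
class ItemResponses:
    """One informant's item-level answers to one instrument."""

    instrument: Instrument
    informant: Informant
    items: tuple[int, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        n_items, max_val = INSTRUMENT_SPECS[Instrument(self.instrument)]
        if len(self.items) != n_items:
            raise ScaleError(
                f"{self.instrument.value}: expected {n_items} items, "
                f"got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if not isinstance(v, (int, np.integer)) or not 0 <= v <= max_val:
                raise ScaleError(
                    f"{self.instrument.value}: item {i} out of range 0-{max_val}: {v!r}"
                )


def _subscale_sum(items: tuple[int, ...], positions: tuple[int, ...]) -> int:
    return int(sum(items[i - 1] for i in positions))


def score_adhd_rs(
    r: ItemResponses,
    inattention_items: tuple[int, ...] = ADHD_INATTENTION_ITEMS,
) -> tuple[int, int, int]:
    """Return (hyperactivity, inattention, total) sums for the ADHD-RS."""
    if Instrument(r.instrument) is not Instrument.ADHD_RS:
        raise ScaleError(f"expected ADHD_RS responses, got {r.instrument}")
    hyper_items = tuple(i for i in range(1, 19) if i not in inattention_items)
    inattention = _subscale_sum(r.items, inattention_items)
    hyperactivity = _subscale_sum(r.items, hyper_items)
    return hyperactivity, inattention, hyperactivity + inattention


def score_ari(r: ItemResponses, items_in_total: int = 6) -> int:
    """ARI symptom total: sum of the first ``items_in_total`` items.

    The default of 6 excludes the final impairment item, the convention
    under which the total ranges 0-12.
    """
    if Instrument(r.instrument) is not Instrument.ARI:
        raise ScaleError(f"expected ARI responses, got {r.instrument}")
    if items_in_total not in (6, 7):
        raise ScaleError("ari items_in_total must be 6 or 7")
    return int(sum(r.items[:items_in_total]))


def score_rpq(
    r: ItemResponses,
    reactive_items: tuple[int, ...] = RPQ_REACTIVE_ITEMS,
) -> tuple[int, int, int]:
    """Return (reactive, proactive, total) sums for the RPQ."""
    if Instrument(r.instrument) is not Instrument.RPQ:
        raise ScaleError(f"expected RPQ responses, got {r.instrument}")
    proactive_items = tuple(i for i in range(1, 24) if i not in reactive_items)
    reactive = _subscale_sum(r.items, reactive_items)
    proactive = _subscale_sum(r.items, proactive_items)
    return reactive, proactive, reactive + proactive


@dataclass(frozen=True)
class ScoreSet:
    """All eleven outcome measures for one child."""

    subject_id: str
    adhd_hyperactivity: int
    adhd_inattention: int
    adhd_total: int
    ari_parent: int
    ari_participant: int
    rpq_parent_reactive: int
    rpq_parent_proactive: int
    rpq_parent_total: int
    rpq_participant_reactive: int
    rpq_participant_proactive: int
    rpq_participant_total: int


#: canonical outcome order, mirroring the descriptive report layout
MEASURES: tuple[str, ...] = tuple(
    f.name for f in fields(ScoreSet) if f.name != "subject_id"
)


def score_subject(
    responses: list[ItemResponses],
    subject_id: str | None = None,
    ari_items_in_total: int = 6,
) -> ScoreSet:
    """Assemble a ScoreSet from one subject's five response records.

    Requires parent ADHD-RS, parent and participant ARI, and parent and
    participant RPQ; a missing combination is an error (exclude the
    subject upstream instead).
    """
    by_key = {(Instrument(r.instrument), Informant(r.informant)): r for r in responses}
    needed = [
        (Instrument.ADHD_RS, Informant.PARENT),
        (Instrument.ARI, Informant.PARENT),
        (Instrument.ARI, Informant.PARTICIPANT),
        (Instrument.RPQ, Informant.PARENT),
        (Instrument.RPQ, Informant.PARTICIPANT),
    ]
    for key in needed:
        if key not in by_key:
            raise ScaleError(
                f"missing responses for {key[0].value}/{key[1].value}"
            )
    if subject_id is None:
        subject_id = responses[0].subject_id

    hyper, inatt, adhd_total = score_adhd_rs(by_key[needed[0]])
    rp = score_rpq(by_key[(Instrument.RPQ, Informant.PARENT)])
    rc = score_rpq(by_key[(Instrument.RPQ, Informant.PARTICIPANT)])
    return ScoreSet(
        subject_id=subject_id,
        adhd_hyperactivity=hyper,
        adhd_inattention=inatt,
        adhd_total=adhd_total,
        ari_parent=score_ari(by_key[(Instrument.ARI, Informant.PARENT)], ari_items_in_total),
        ari_participant=score_ari(
            by_key[(Instrument.ARI, Informant.PARTICIPANT)], ari_items_in_total
        ),
        rpq_parent_reactive=rp[0],
        rpq_parent_proactive=rp[1],
        rpq_parent_total=rp[2],
        rpq_participant_reactive=rc[0],
        rpq_participant_proactive=rc[1],
        rpq_participant_total=rc[2],
    )


def scores_to_frame(score_sets: list[ScoreSet]) -> pd.DataFrame:
    """Subjects x measures table, indexed by subject_id."""
    rows = [
        {"subject_id": s.subject_id, **{m: getattr(s, m) for m in MEASURES}}
        for s in score_sets
    ]
    return pd.DataFrame(rows).set_index("subject_id")


def descriptives(score_sets: list[ScoreSet]) -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) per outcome measure."""
    if len(score_sets) < 2:
        raise ScaleError("descriptives need at least 2 subjects for an SD")
    frame = scores_to_frame(score_sets)
    return pd.DataFrame(
        {
            "measure": MEASURES,
            "mean": [float(frame[m].mean()) for m in MEASURES],
            "sd": [float(frame[m].std(ddof=1)) for m in MEASURES],
        }
    )


_MAX_ITEMS = max(n for n, _ in INSTRUMENT_SPECS.values())


def write_item_responses(responses: list[ItemResponses], path: str | Path) -> None:
    """Write item-level responses as a wide CSV (blank cells pad short scales)."""
    cols = ["subject_id", "instrument", "informant"] + [
        f"item_{i:02d}" for i in range(1, _MAX_ITEMS + 1)
    ]
    rows = []
    for r in responses:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "instrument": Instrument(r.instrument).value,
            "informant": Informant(r.informant).value,
        }
        for i, v in enumerate(r.items, start=1):
            row[f"item_{i:02d}"] = v
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_item_responses(path: str | Path) -> list[ItemResponses]:
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        instrument = Instrument(row["instrument"])
        n_items, _ = INSTRUMENT_SPECS[instrument]
        items = tuple(int(row[f"item_{i:02d}"]) for i in range(1, n_items + 1))
        out.append(
            ItemResponses(
                instrument=instrument,
                informant=Informant(row["informant"]),
                items=items,
                subject_id=str(row["subject_id"]),
            )
        )
    return out
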