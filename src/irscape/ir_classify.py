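"""Seven-way sequence classification of inverted-repeat arms.

Each IR is typed from three binary predicates evaluated on one repeat unit
(the 5' arm; spacer bases are ignored):

* **AT-rich** — arm AT content >= 0.6 (just above the ~0.62 genomic AT
  fraction of *S. cerevisiae*, so "AT-rich" means richer than background);
* **tract-rich** — the longest run of >= 3 consecutive A's, or of T's,
  covers >= 0.5 of the arm;
* **alternating-rich** — the longest exact ``(AT)n`` or ``(TA)n`` substring
  (complete dinucleotide units only, so even length) covers >= 0.5 of the
  arm.

The (at, tract, alt) triple maps onto seven types::

    (T,T,T) -> I     (T,T,F) -> II    (T,F,T) -> III   (T,F,F) -> IV
    (F,T,F) -> V     (F,T,T) -> VI    (F,F,T) -> VI    (F,F,F) -> VII

Types I, II, III, V and VII match their verbal definitions (II =
A/T-tract-rich AT-rich arms, III = alternating-AT AT-rich arms, VII = none
of the predicates, ...).  The assignment of (T,F,F) to IV and the merger of
the two non-AT-rich alternating combinations into VI are inferred by
elimination so that the eight predicate combinations land on exactly seven
mutually exclusive, exhaustive types; see docs/methods.md.

Both tract and alternation predicates are written as "A or T" disjunctions,
so classifying the right arm (which swaps A<->T) never changes the label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ir_scan import IRecord

TYPE_IDS = ("I", "II", "III", "IV", "V", "VI", "VII")

#: (at_rich, tract_rich, alt_rich) -> type id
TYPE_FROM_FLAGS = {
    (True, True, True): "I",
    (True, True, False): "II",
    (True, False, True): "III",
    (True, False, False): "IV",
    (False, True, False): "V",
    (False, True, True): "VI",
    (False, False, True): "VI",
    (False, False, False): "VII",
}

_ALT_RE = re.compile(r"(?:AT)+|(?:TA)+")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Classification cut-offs (defaults are the standard ones)."""

    at_rich: float = 0.6
    occupancy: float = 0.5
    min_tract: int = 3


@dataclass(frozen=True)
class ArmFeatures:
    at_content: float
    tract_occupancy: float
    alt_occupancy: float


@dataclass(frozen=True)
class IRTypeLabel:
    type_id: str
    at_rich: bool
    tract_rich: bool
    alt_rich: bool


def arm_features(
    left_arm_seq: str, min_tract: int = 3
) -> ArmFeatures:
    """Compute AT content, A/T-tract occupancy and alternating-AT occupancy
    of one repeat unit.

    Occupancies are the length of the longest qualifying substring divided
    by the arm length; 0 when no qualifying substring exists.  Arms cannot
    contain N (no base pairs with N), so N here signals an upstream bug.
    """
    if not left_arm_seq:
        raise ValueError("empty arm")
    arm = left_arm_seq.upper()
    if set(arm) - set("ACGT"):
        raise ValueError(f"arm contains non-ACGT characters: {left_arm_seq!r}")
    n = len(arm)
    at = (arm.count("A") + arm.count("T")) / n

    tract_re = re.compile(r"A{%d,}|T{%d,}" % (min_tract, min_tract))
    tract = max((len(m) for m in tract_re.findall(arm)), default=0)
    alt = max((len(m) for m in _ALT_RE.findall(arm)), default=0)
    return ArmFeatures(at, tract / n, alt / n)


def classify(
    features: ArmFeatures, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> IRTypeLabel:
    """Map arm features to one of the seven IR types."""
    flags = (
        features.at_content >= thresholds.at_rich,
        features.tract_occupancy >= thresholds.occupancy,
        features.alt_occupancy >= thresholds.occupancy,
    )
    return IRTypeLabel(TYPE_FROM_FLAGS[flags], *flags)


def classify_arm(
    left_arm_seq: str, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> IRTypeLabel:
    return classify(arm_features(left_arm_seq, thresholds.min_tract), thresholds)


def classify_irs(
    irs: Sequence[IRecord],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Classify a list of IRs into a tidy table.

    Columns: the IRecord fields plus at_content, tract_occupancy,
    alt_occupancy and type_id.
    """
    rows = []
    for rec in irs:
        feats = arm_features(rec.left_arm_seq, thresholds.min_tract)
        label = classify(feats, thresholds)
        rows.append(
            {
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "arm_len": rec.arm_len,
                "spacer_len": rec.spacer_len,
                "center": rec.center,
                "left_arm_seq": rec.left_arm_seq,
                "at_content": feats.at_content,
                "tract_occupancy": feats.tract_occupancy,
                "alt_occupancy": feats.alt_occupancy,
                "type_id": label.type_id,
            }
        )
    columns = [
        "chrom", "start", "end", "arm_len", "spacer_len", "center",
        "left_arm_seq", "at_content", "tract_occupancy", "alt_occupancy",
        "type_id",
    ]
    return pd.DataFrame(rows, columns=columns)


def type_filter(type_id: str, thresholds: ClassifierThresholds = ClassifierThresholds()):
    """Predicate selecting IRs of one type (for type-resolved profiles)."""
    if type_id not in TYPE_IDS:
        raise ValueError(f"unknown IR type {type_id!r}")

    def _pred(rec: IRecord) -> bool:
        return classify_arm(rec.left_arm_seq, thresholds).type_id == type_id

    return _pred
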