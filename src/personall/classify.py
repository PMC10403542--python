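"""The two patient classifiers.

* IKAROS classifier: a cytogenetics-aware interpretation of *IKZF1* status.
  The subtype maps to a cytogenetic risk class (good / intermediate /
  poor), and the (risk class x IKZF1 status) cell of a lookup matrix gives
  the IKAROS-low / -medium / -high group.
* PersonALL classifier: the patient's cumulative score — the sum of the
  score-table weights over all matching lesions, with exclusion groups
  preventing double counting — is thresholded into four prognostic groups:
  excellent (score >= 4), good (0-3), high (-3..-1) and ultra-poor (<= -4).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .profiles import IkzfStatus, LesionProfile, SUBTYPE_PRECEDENCE
from .scoring import ScoreTable

__all__ = [
    "PersonallGroup",
    "IkarosGroup",
    "IkarosMatrix",
    "RiskAssignment",
    "DEFAULT_IKAROS_MATRIX",
    "classify_ikaros",
    "cumulative_score",
    "classify_personall",
    "classify_cohort",
]


class PersonallGroup(str, enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    HIGH = "high"
    ULTRA_POOR = "ultra_poor"


class IkarosGroup(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


_RISK_CLASSES = ("good", "intermediate", "poor")


@dataclass(frozen=True)
class IkarosMatrix:
    """Total lookup (cytogenetic risk class x IKZF1 status) -> IKAROS group."""

    subtype_risk: Mapping[str, str]  # subtype label -> risk class
    mapping: Mapping[tuple[str, str], IkarosGroup]  # (risk class, status) -> group

    def __post_init__(self) -> None:
        bad = set(self.subtype_risk.values()) - set(_RISK_CLASSES)
        if bad:
            raise ValueError(f"unknown cytogenetic risk classes: {sorted(bad)}")
        statuses = [s.value for s in IkzfStatus]
        missing = [
            (rc, st)
            for rc in _RISK_CLASSES
            for st in statuses
            if (rc, st) not in self.mapping
        ]
        if missing:
            raise ValueError(f"IKAROS matrix is not total; missing cells: {missing}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "IkarosMatrix":
        unknown = set(d) - {"subtype_risk", "mapping"}
        if unknown:
            raise ValueError(f"unknown IKAROS config keys: {sorted(unknown)}")
        mapping = {}
        for rc, row in d["mapping"].items():
            for status, group in row.items():
                mapping[(rc, status)] = IkarosGroup(group)
        return cls(subtype_risk=dict(d["subtype_risk"]), mapping=mapping)

    def to_dict(self) -> dict:
        rows: dict[str, dict[str, str]] = {}
        for (rc, status), group in self.mapping.items():
            rows.setdefault(rc, {})[status] = group.value
        return {"subtype_risk": dict(self.subtype_risk), "mapping": rows}


#: Default combination matrix. Risk classes follow the established
#: cytogenetic categories (ETV6-RUNX1 and high-hyperdiploidy good;
#: BCR-ABL1, Ph-like, KMT2A-r and iAMP21 poor; the rest intermediate).
#: An intact IKZF1 is always IKAROS-low; a plain deletion is only escalated
#: outside the good class; IKZF1plus escalates one step further.
DEFAULT_IKAROS_MATRIX = IkarosMatrix(
    subtype_risk={
        "ETV6-RUNX1": "good",
        "HHD": "good",
        "BCR-ABL1": "poor",
        "Ph-like": "poor",
        "KMT2A-r": "poor",
        "iAMP21": "poor",
        "TCF3-PBX1": "intermediate",
        "B-other": "intermediate",
    },
    mapping={
        ("good", "normal"): IkarosGroup.LOW,
        ("intermediate", "normal"): IkarosGroup.LOW,
        ("poor", "normal"): IkarosGroup.LOW,
        ("good", "del"): IkarosGroup.LOW,
        ("intermediate", "del"): IkarosGroup.MEDIUM,
        ("poor", "del"): IkarosGroup.MEDIUM,
        ("good", "plus"): IkarosGroup.MEDIUM,
        ("intermediate", "plus"): IkarosGroup.HIGH,
        ("poor", "plus"): IkarosGroup.HIGH,
    },
)


@dataclass(frozen=True)
class RiskAssignment:
    patient_id: str
    cumulative_score: int
    personall_group: PersonallGroup
    ikaros_group: IkarosGroup


def classify_ikaros(
    status: IkzfStatus, subtype: str, matrix: IkarosMatrix = DEFAULT_IKAROS_MATRIX
) -> IkarosGroup:
    """Pure table lookup of the IKAROS group."""
    if subtype not in matrix.subtype_risk:
        raise ValueError(f"subtype {subtype!r} not mapped to a cytogenetic risk class")
    return matrix.mapping[(matrix.subtype_risk[subtype], status.value)]


def cumulative_score(profile: LesionProfile, table: ScoreTable) -> int:
    """Sum of score-table weights over the profile's matching lesions.

    Within each exclusion group only the first (most specific) matching
    entry contributes; lesions without a table entry contribute 0.
    """
    matched = [e.lesion for e in table.entries if e.lesion in profile.lesions]
    superseded: set[str] = set()
    for group in table.exclusion_groups:
        hits = [l for l in group if l in matched]
        superseded.update(hits[1:])
    return sum(
        table.entry(l).score for l in matched if l not in superseded
    )


def classify_personall(score: int) -> PersonallGroup:
    """Threshold the cumulative score into one of the four risk groups.

    The published ranges are excellent >= 4, good 0-3, high -1 to -4 and
    ultra-poor <= -4; the overlapping boundary -4 is resolved to ultra-poor
    so the ranges partition the integers.
    """
    if score >= 4:
        return PersonallGroup.EXCELLENT
    if score >= 0:
        return PersonallGroup.GOOD
    if score >= -3:
        return PersonallGroup.HIGH
    return PersonallGroup.ULTRA_POOR


def classify_cohort(
    profiles: Sequence[LesionProfile],
    table: ScoreTable,
    matrix: IkarosMatrix = DEFAULT_IKAROS_MATRIX,
) -> pd.DataFrame:
    """Risk assignment for every profile.

    Returns a DataFrame with columns
    ``patient_id score personall_group ikaros_group``.
    """
    rows = []
    for p in profiles:
        s = cumulative_score(p, table)
        rows.append(
            dict(
                patient_id=p.patient_id,
                score=s,
                personall_group=classify_personall(s).value,
                ikaros_group=classify_ikaros(p.ikzf_status, p.subtype, matrix).value,
            )
        )
    return pd.DataFrame(rows, columns=["patient_id", "score", "personall_group", "ikaros_group"])
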