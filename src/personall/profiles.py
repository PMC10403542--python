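"""Per-patient genetic profiles: lesions, composite genotypes, subtypes.

A profile is a set of canonical lesion tokens merged from three sources:
gene-level copy-number calls, the digital karyotype (whole-chromosome
gains), and externally provided fusion/cytogenetic markers. Composite
genotypes (IKZF1plus, double trisomy 4+6, high-hyperdiploidy) are derived
here so downstream scoring can treat them as first-class lesions.

Token conventions
-----------------
``GENE:loss`` / ``GENE:gain``          gene-level CNA (a biallelic loss also
                                       carries ``GENE:biallelic_loss``, a
                                       multiple gain ``GENE:multiple_gain``)
``+4`` ...                             whole-chromosome gain (copy number >= 3)
``ETV6-RUNX1`` ...                     subgroup-defining fusion / genotype
``IKZF1plus`` ``DT4_6`` ``HHD``        composite flags
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .caller import Clonality, CnaCall, CnaState, KaryotypeEstimate, PloidyClass

logger = logging.getLogger(__name__)

__all__ = [
    "FUSION_MARKERS",
    "SUBTYPE_PRECEDENCE",
    "IkzfStatus",
    "PatientRecord",
    "LesionProfile",
    "assign_ikzf1_status",
    "assign_cytogenetic_subtype",
    "detect_trisomy_combinations",
    "build_profile",
]

#: Recognised subgroup-defining markers as supplied in clinical tables.
FUSION_MARKERS = frozenset(
    {"ETV6-RUNX1", "BCR-ABL1", "TCF3-PBX1", "KMT2A-r", "iAMP21", "Ph-like-marker"}
)

#: Adverse fusion genotypes dominate assignment; HHD only applies when no
#: subgroup-defining fusion is present, and B-other is the residual class.
SUBTYPE_PRECEDENCE = (
    "BCR-ABL1",
    "KMT2A-r",
    "Ph-like",
    "TCF3-PBX1",
    "iAMP21",
    "ETV6-RUNX1",
    "HHD",
    "B-other",
)

#: Loci that must have been assessed before IKZF1 status can be assigned.
IKZF1_STATUS_LOCI = ("IKZF1", "CDKN2A/B", "PAX5", "PAR1", "ERG")

#: Default trisomy combinations screened for favorable outcome.
DEFAULT_TRISOMY_COMBOS: dict[str, frozenset[str]] = {"DT4_6": frozenset({"4", "6"})}


class IkzfStatus(str, enum.Enum):
    NORMAL = "normal"
    DEL = "del"
    PLUS = "plus"


@dataclass(frozen=True)
class PatientRecord:
    """Clinical record of one patient.

    ``efs_months`` is event-free survival time (months from treatment start
    to relapse, second malignancy or disease-related death); ``event`` is 1
    if such an event occurred, 0 if censored.
    """

    patient_id: str
    age_years: float
    sex: str
    purity: float
    fusion_markers: frozenset[str] = frozenset()
    efs_months: float = 0.0
    event: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"{self.patient_id}: purity must be in (0, 1]")
        if self.efs_months < 0:
            raise ValueError(f"{self.patient_id}: efs_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")
        unknown = set(self.fusion_markers) - FUSION_MARKERS
        if unknown:
            raise ValueError(f"{self.patient_id}: unknown fusion markers {sorted(unknown)}")


@dataclass(frozen=True)
class LesionProfile:
    """Set of lesion tokens for one patient, plus derived annotations."""

    patient_id: str
    lesions: frozenset[str]
    assessed_loci: frozenset[str] = frozenset()
    subtype: str = "B-other"
    ikzf_status: IkzfStatus = IkzfStatus.NORMAL

    def __contains__(self, lesion: str) -> bool:
        return lesion in self.lesions


def _ikzf1_status_from(lesions: Iterable[str], assessed: Iterable[str]) -> IkzfStatus:
    assessed = set(assessed)
    missing = [l for l in IKZF1_STATUS_LOCI if l not in assessed]
    if missing:
        raise ValueError(f"IKZF1 status requires calls for loci: {missing}")
    lesions = set(lesions)
    if "IKZF1:loss" not in lesions:
        return IkzfStatus.NORMAL
    partner = {"CDKN2A/B:loss", "PAX5:loss", "PAR1:loss"}
    if lesions & partner and "ERG:loss" not in lesions:
        return IkzfStatus.PLUS
    return IkzfStatus.DEL


def assign_ikzf1_status(profile: LesionProfile) -> IkzfStatus:
    """IKZF1 genotype class of a profile.

    ``plus`` requires an *IKZF1* deletion together with a *CDKN2A/B*, *PAX5*
    or PAR1 deletion and no *ERG* deletion; an *IKZF1* deletion not meeting
    those criteria is ``del``; otherwise ``normal``.
    """
    return _ikzf1_status_from(profile.lesions, profile.assessed_loci)


def assign_cytogenetic_subtype(
    record: PatientRecord, karyotype: KaryotypeEstimate | None
) -> str:
    """One subgroup label per patient, by fixed precedence.

    Subgroup-defining fusions/genotypes outrank the high-hyperdiploid
    karyotype; patients matching nothing are B-other. When several
    subgroup-defining markers co-occur the highest-precedence one wins and
    the conflict is logged.
    """
    present = {m if m != "Ph-like-marker" else "Ph-like" for m in record.fusion_markers}
    if karyotype is not None and karyotype.ploidy_class is PloidyClass.HIGH_HYPERDIPLOID:
        present.add("HHD")
    matches = [s for s in SUBTYPE_PRECEDENCE[:-1] if s in present]
    if len([m for m in matches if m != "HHD"]) > 1:
        logger.warning(
            "%s: multiple subgroup-defining markers %s; keeping %s",
            record.patient_id, matches, matches[0],
        )
    return matches[0] if matches else "B-other"


def detect_trisomy_combinations(
    karyotype: KaryotypeEstimate,
    combos: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, bool]:
    """Flag each chromosome-set combo whose members all have copy number >= 3."""
    combos = combos if combos is not None else DEFAULT_TRISOMY_COMBOS
    out = {}
    for name, chroms in combos.items():
        out[name] = all(karyotype.copy_numbers.get(str(c), 2) >= 3 for c in chroms)
    return out


def build_profile(
    record: PatientRecord,
    calls: Sequence[CnaCall],
    karyotype: KaryotypeEstimate | None = None,
    min_clonality: str = "subclonal",
    trisomy_combos: Mapping[str, Iterable[str]] | None = None,
) -> LesionProfile:
    """Merge calls, karyotype and fusion markers into one lesion profile.

    ``min_clonality="clonal"`` drops subclonal calls from the profile (the
    default keeps them). The result is independent of the order of
    ``calls``; two calls for the same locus are an error.
    """
    if min_clonality not in ("clonal", "subclonal"):
        raise ValueError("min_clonality must be 'clonal' or 'subclonal'")
    seen: dict[str, CnaCall] = {}
    for c in calls:
        if c.locus in seen:
            raise ValueError(f"{record.patient_id}: duplicate calls for locus {c.locus}")
        seen[c.locus] = c

    lesions: set[str] = set()
    for c in seen.values():
        if c.state is CnaState.NORMAL:
            continue
        if min_clonality == "clonal" and c.clonality is Clonality.SUBCLONAL:
            continue
        if c.state in (CnaState.LOSS, CnaState.BIALLELIC_LOSS):
            lesions.add(f"{c.locus}:loss")
            if c.state is CnaState.BIALLELIC_LOSS:
                lesions.add(f"{c.locus}:biallelic_loss")
        else:
            lesions.add(f"{c.locus}:gain")
            if c.state is CnaState.MULTIPLE_GAIN:
                lesions.add(f"{c.locus}:multiple_gain")

    if karyotype is not None:
        for chrom, cn in karyotype.copy_numbers.items():
            if cn >= 3:
                lesions.add(f"+{chrom}")
        for name, flag in detect_trisomy_combinations(karyotype, trisomy_combos).items():
            if flag:
                lesions.add(name)

    lesions |= {m if m != "Ph-like-marker" else "Ph-like" for m in record.fusion_markers}

    subtype = assign_cytogenetic_subtype(record, karyotype)
    if subtype != "B-other":
        lesions.add(subtype)

    assessed = frozenset(seen)
    status = IkzfStatus.NORMAL
    if all(l in assessed for l in IKZF1_STATUS_LOCI):
        status = _ikzf1_status_from(lesions, assessed)
        if status is IkzfStatus.PLUS:
            lesions.add("IKZF1plus")

    return LesionProfile(
        patient_id=record.patient_id,
        lesions=frozenset(lesions),
        assessed_loci=assessed,
        subtype=subtype,
        ikzf_status=status,
    )
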