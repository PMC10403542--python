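"""Deriving per-lesion prognostic scores from a cohort.

The derivation is a three-stage pipeline run per candidate lesion:

1. univariate Cox fit of the lesion carrier indicator against event-free
   survival (truncated at 60 months),
2. a selection filter keeping lesions with cohort frequency > 1.5% and a
   hazard ratio > 1.5 (adverse) or <= 0.66 (protective),
3. a signed integer weight proportional to the log hazard ratio:
   magnitude ``clamp(round(|ln HR| / ln 1.5), 1, 4)``, positive for
   protective and negative for adverse lesions.

A hand-set score table (e.g. a published supplementary weighting) can be
loaded from JSON instead of being derived; the schema is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cox import CoxFit, fit_univariate_cox
from .profiles import LesionProfile, PatientRecord

__all__ = [
    "ScoreEntry",
    "ScoreTable",
    "DeriveConfig",
    "carrier_matrix",
    "select_prognostic_lesions",
    "assign_lesion_score",
    "derive_score_table",
]


@dataclass(frozen=True)
class ScoreEntry:
    """One lesion predicate with its signed weight and selection metadata."""

    lesion: str
    score: int
    provenance: str = "config"
    hr: float | None = None
    freq: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.score, (int, np.integer)) or isinstance(self.score, bool):
            raise ValueError(f"{self.lesion}: score must be an integer")
        if self.score == 0:
            raise ValueError(f"{self.lesion}: score must be non-zero")


@dataclass
class ScoreTable:
    """Lesion -> signed score mapping with exclusion groups.

    Each exclusion group is ordered most-specific-first; when several
    entries of one group match a profile, only the first matching one
    contributes (e.g. ``IKZF1plus`` supersedes the plain ``IKZF1:loss``).
    """

    entries: list[ScoreEntry]
    exclusion_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.lesion in seen:
                raise ValueError(f"duplicate score entry for {e.lesion}")
            seen.add(e.lesion)
        for group in self.exclusion_groups:
            unknown = [l for l in group if l not in seen]
            if unknown:
                raise ValueError(f"exclusion group references unknown lesions: {unknown}")

    @property
    def lesions(self) -> list[str]:
        return [e.lesion for e in self.entries]

    def entry(self, lesion: str) -> ScoreEntry:
        for e in self.entries:
            if e.lesion == lesion:
                return e
        raise KeyError(lesion)

    def to_dict(self) -> dict:
        entries = []
        for e in self.entries:
            d = {k: v for k, v in asdict(e).items() if v is not None}
            entries.append(d)
        return {"entries": entries, "exclusion_groups": [list(g) for g in self.exclusion_groups]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreTable":
        unknown = set(d) - {"entries", "exclusion_groups"}
        if unknown:
            raise ValueError(f"unknown score table keys: {sorted(unknown)}")
        allowed = set(ScoreEntry.__dataclass_fields__)
        entries = []
        for raw in d.get("entries", []):
            bad = set(raw) - allowed
            if bad:
                raise ValueError(f"unknown score entry keys: {sorted(bad)}")
            if "score" in raw and (not isinstance(raw["score"], int) or isinstance(raw["score"], bool)):
                raise ValueError(f"{raw.get('lesion')}: score must be an integer")
            entries.append(ScoreEntry(**raw))
        return cls(entries=entries, exclusion_groups=[list(g) for g in d.get("exclusion_groups", [])])


@dataclass(frozen=True)
class DeriveConfig:
    """Configuration of the score-derivation pipeline."""

    f_min: float = 0.015
    hr_hi: float = 1.5
    hr_lo: float = 0.66
    ties: str = "efron"
    truncate_months: float = 60.0
    weight_base: float = 1.5
    max_magnitude: int = 4
    candidate_lesions: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "DeriveConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown derive config keys: {sorted(unknown)}")
        d = dict(d)
        if "candidate_lesions" in d and d["candidate_lesions"] is not None:
            d["candidate_lesions"] = tuple(d["candidate_lesions"])
        return cls(**d)


def carrier_matrix(
    profiles: Sequence[LesionProfile], lesions: Iterable[str] | None = None
) -> pd.DataFrame:
    """Patients x lesions boolean indicator matrix."""
    if lesions is None:
        lesions = sorted(set().union(*(p.lesions for p in profiles)) if profiles else set())
    lesions = list(lesions)
    data = {l: [l in p.lesions for p in profiles] for l in lesions}
    return pd.DataFrame(data, index=[p.patient_id for p in profiles], dtype=bool)


def select_prognostic_lesions(
    fits: Sequence[CoxFit],
    cohort_n: int,
    f_min: float = 0.015,
    hr_hi: float = 1.5,
    hr_lo: float = 0.66,
) -> list[CoxFit]:
    """Keep lesions with frequency > ``f_min`` and HR > ``hr_hi`` or <= ``hr_lo``.

    Comparison strictness follows the published filter exactly: frequency
    strictly greater, adverse HR strictly greater, protective HR inclusive.
    """
    selected = []
    for fit in fits:
        freq = fit.n_carriers / cohort_n
        if freq > f_min and (fit.hr > hr_hi or fit.hr <= hr_lo):
            selected.append(fit)
    return selected


def assign_lesion_score(
    fit: CoxFit,
    hr_hi: float = 1.5,
    hr_lo: float = 0.66,
    weight_base: float = 1.5,
    max_magnitude: int = 4,
) -> int:
    """Signed integer weight from a selected lesion's hazard ratio.

    Magnitude is the log hazard ratio in units of ``ln(weight_base)``,
    rounded half away from zero and clamped to ``[1, max_magnitude]``;
    protective lesions (HR <= ``hr_lo``) score positive, adverse lesions
    (HR > ``hr_hi``) negative. A lesion inside the neutral band must not be
    scored and raises.
    """
    hr = fit.hr
    if hr_lo < hr <= hr_hi:
        raise ValueError(f"{fit.lesion}: HR {hr:.3f} inside the neutral band, not scorable")
    magnitude = int(math.floor(abs(math.log(hr)) / math.log(weight_base) + 0.5))
    magnitude = min(max(magnitude, 1), max_magnitude)
    return magnitude if hr <= hr_lo else -magnitude


def _default_exclusion_groups(lesions: Iterable[str]) -> list[list[str]]:
    """Most-specific-first groups for nested lesion predicates.

    A composite supersedes its components so one biological event is not
    counted twice: IKZF1plus over the plain IKZF1 loss, biallelic losses
    and multiple gains over their single-copy forms, the 4+6 double
    trisomy over the individual trisomies, and the high-hyperdiploidy
    flag over every single whole-chromosome gain.
    """
    lesions = set(lesions)
    groups: list[list[str]] = []
    if {"IKZF1plus", "IKZF1:loss"} <= lesions:
        groups.append(["IKZF1plus", "IKZF1:loss"])
    for l in sorted(lesions):
        for specific, generic in ((":biallelic_loss", ":loss"), (":multiple_gain", ":gain")):
            if l.endswith(specific):
                base = l[: -len(specific)] + generic
                if base in lesions:
                    groups.append([l, base])
        if l.startswith("+"):
            if "DT4_6" in lesions and l in ("+4", "+6"):
                groups.append(["DT4_6", l])
            if "HHD" in lesions:
                groups.append(["HHD", l])
    return groups


def derive_score_table(
    profiles: Sequence[LesionProfile],
    records: Sequence[PatientRecord],
    config: DeriveConfig | None = None,
) -> tuple[ScoreTable, list[CoxFit]]:
    """Fit, filter and weight every recurrent lesion of a cohort.

    Returns the derived table together with all univariate fits (selected
    or not) for reporting. Profiles and records are aligned by patient id;
    EFS is truncated at ``config.truncate_months`` before fitting.
    """
    config = config or DeriveConfig()
    by_id = {r.patient_id: r for r in records}
    if set(p.patient_id for p in profiles) - set(by_id):
        raise ValueError("profiles contain patient_ids absent from records")
    recs = [by_id[p.patient_id] for p in profiles]
    if sum(r.event for r in recs) == 0:
        raise ValueError("cohort has zero events")

    t_cut = config.truncate_months
    time = np.array([min(r.efs_months, t_cut) for r in recs])
    event = np.array([r.event if r.efs_months <= t_cut else 0 for r in recs])

    candidates = (
        sorted(config.candidate_lesions)
        if config.candidate_lesions is not None
        else sorted(set().union(*(p.lesions for p in profiles)))
    )
    X = carrier_matrix(profiles, candidates)

    fits: list[CoxFit] = []
    for lesion in candidates:
        x = X[lesion].to_numpy(dtype=float)
        if x.min() == x.max():
            continue
        fits.append(fit_univariate_cox(x, time, event, lesion=lesion, ties=config.ties))

    # separation-flagged fits (monotone likelihood, capped beta) carry no
    # usable effect size and are reported but never scored
    selected = select_prognostic_lesions(
        [f for f in fits if not f.flagged], cohort_n=len(profiles),
        f_min=config.f_min, hr_hi=config.hr_hi, hr_lo=config.hr_lo,
    )
    entries = []
    for fit in selected:
        score = assign_lesion_score(
            fit, hr_hi=config.hr_hi, hr_lo=config.hr_lo,
            weight_base=config.weight_base, max_magnitude=config.max_magnitude,
        )
        lo, hi = fit.ci95
        entries.append(
            ScoreEntry(
                lesion=fit.lesion, score=score, provenance="derived",
                hr=fit.hr, freq=fit.n_carriers / len(profiles),
                ci_low=lo, ci_high=hi, p_value=fit.p_value,
            )
        )
    table = ScoreTable(
        entries=entries,
        exclusion_groups=_default_exclusion_groups([e.lesion for e in entries]),
    )
    return table, fits
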