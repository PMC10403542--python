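"""Copy-number calling from digitalMLPA-style probe read counts.

The pipeline is: raw read counts -> two-step normalization into dosage
quotients (DQ) -> purity-aware gene/arm level calls.

A dosage quotient sits near 1.0 for a copy-neutral locus. With a blast
purity (leukemic-cell fraction) of ``p``, the expected DQ of a clonal
aberration is diluted toward 1.0 by the non-leukemic cells::

    biallelic loss   1 - p
    monoallelic loss 1 - p/2
    one-copy gain    1 + p/2
    multiple gain    >= 1 + p

Subclonal lesions (present in only a fraction of the blasts) fall between
the normal band and the expected clonal level, which is how they are
recognised here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ACROCENTRIC, CHROMOSOMES, IKZF1_PROBE_ORDER, ProbePanel

__all__ = [
    "CnaState",
    "Clonality",
    "PloidyClass",
    "CnaCall",
    "KaryotypeEstimate",
    "CallerConfig",
    "DosageMatrix",
    "normalize_read_counts",
    "call_gene_cna",
    "call_sample",
    "call_cohort",
    "ikzf1_deletion_pattern",
    "digital_karyotype",
    "arm_dosage",
]


class CnaState(str, enum.Enum):
    NORMAL = "normal"
    LOSS = "loss"
    BIALLELIC_LOSS = "biallelic_loss"
    GAIN = "gain"
    MULTIPLE_GAIN = "multiple_gain"


class Clonality(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"


class PloidyClass(str, enum.Enum):
    NON_HYPERDIPLOID = "non_hyperdiploid"
    HIGH_HYPERDIPLOID = "high_hyperdiploid"
    NEAR_TRIPLOID = "near_triploid"
    OTHER = "other"


@dataclass(frozen=True)
class CnaCall:
    """A gene- or arm-level copy-number call in one sample."""

    locus: str
    state: CnaState
    clonality: Clonality
    n_probes_supporting: int
    mean_dq: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state is CnaState.NORMAL and self.clonality is not Clonality.CLONAL:
            raise ValueError("a normal call cannot be subclonal")


@dataclass(frozen=True)
class KaryotypeEstimate:
    """Whole-genome copy-number summary from digital-karyotyping probes."""

    copy_numbers: Mapping[str, int]
    modal_number: int
    ploidy_class: PloidyClass
    structural: tuple[str, ...] = ()


@dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the copy-number caller.

    normal_band_floor
        Minimal half-width of the copy-neutral DQ band around 1.0.
    robust_sd_mult
        The band is widened to ``robust_sd_mult`` x the per-probe robust SD
        observed across reference samples, when that exceeds the floor.
    level_tolerance
        Half-width (DQ units) for matching a purity-expected clonal level;
        a deviation beyond the band but short of the level by more than
        this is a subclonal call.
    min_consecutive
        Aberrant-probe run length required for a call in genes with >= 2
        probes; suppresses single-probe noise.
    single_probe_threshold
        Absolute DQ deviation required to call a single-probe gene.
    control_cv_max
        Per-sample QC: coefficient of variation of the control probes'
        relative read counts must not exceed this.
    """

    normal_band_floor: float = 0.15
    robust_sd_mult: float = 3.0
    level_tolerance: float = 0.10
    min_consecutive: int = 2
    single_probe_threshold: float = 0.30
    control_cv_max: float = 0.25

    @classmethod
    def from_dict(cls, d: Mapping) -> "CallerConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown caller config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class DosageMatrix:
    """Per-probe, per-sample dosage quotients plus reference-sample metadata."""

    dq: pd.DataFrame = field(repr=False)  # probes x samples
    reference_sample_ids: list[str]
    probe_noise: pd.Series = field(repr=False)  # robust SD across reference samples
    excluded_samples: list[str] = field(default_factory=list)
    sample_qc: pd.DataFrame | None = field(default=None, repr=False)


def _control_cv(counts: pd.DataFrame, panel: ProbePanel) -> pd.Series:
    """Per-sample coefficient of variation of control-probe signals.

    Each control probe's relative count is first divided by its cohort
    median so fixed per-probe efficiency differences do not inflate the CV;
    what remains measures sample-specific noise.
    """
    ctrl = counts.loc[counts.index.intersection(panel.control_probe_ids)]
    ref = counts.loc[panel.reference_probe_ids]
    rel = ctrl / ref.median(axis=0)
    probe_typical = rel.median(axis=1)
    ratio = rel.div(probe_typical, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = ratio.std(axis=0, ddof=1) / ratio.mean(axis=0)
    return cv.fillna(0.0)


def normalize_read_counts(
    counts: pd.DataFrame,
    panel: ProbePanel,
    reference_samples: Sequence[str],
    config: CallerConfig | None = None,
) -> DosageMatrix:
    """Two-step normalization of raw probe read counts into dosage quotients.

    Step 1 computes each sample's scaling factor as the median, over the
    reference probes, of the probe's count divided by that probe's own
    baseline (its median count across the reference samples); dividing by
    this factor gives the relative read count (intra-sample
    normalization). Step 2 divides each relative count by the median of
    the matching values across the reference samples (inter-sample
    normalization). Taking the step-1 median on the ratio scale makes the
    factor insensitive to per-probe efficiency differences, so the
    baseline holds even when a sizable minority of reference probes sits
    on gained chromosomes (hyperdiploid genomes); with equal probe
    efficiencies it coincides with the plain median of reference-probe
    counts. Medians are used throughout for outlier robustness.

    Samples whose total reference-probe count is zero are excluded and
    recorded in ``excluded_samples``; a probe present in ``counts`` but not
    in the panel is a hard error.
    """
    config = config or CallerConfig()
    if len(reference_samples) == 0:
        raise ValueError("at least one reference sample is required")
    missing = set(reference_samples) - set(counts.columns)
    if missing:
        raise ValueError(f"reference samples absent from counts: {sorted(missing)}")
    unknown_probes = set(counts.index) - set(panel.probe_ids)
    if unknown_probes:
        raise ValueError(f"probes absent from panel: {sorted(unknown_probes)[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")

    counts = counts.astype(float)
    ref_probe_totals = counts.loc[panel.reference_probe_ids].sum(axis=0)
    excluded = ref_probe_totals.index[ref_probe_totals <= 0].tolist()
    bad_refs = sorted(set(excluded) & set(reference_samples))
    if bad_refs:
        raise ValueError(f"reference samples with zero reference-probe counts: {bad_refs}")

    cv = _control_cv(counts, panel)
    failing_refs = [s for s in reference_samples if cv[s] > config.control_cv_max]
    if failing_refs:
        raise ValueError(
            f"reference samples failing control-probe QC (CV > "
            f"{config.control_cv_max}): {failing_refs}"
        )

    kept = counts.drop(columns=excluded)
    # step 1: per-sample scaling from reference-probe ratios to their own
    # cross-reference-sample baselines (efficiency-free median)
    ref_counts = kept.loc[panel.reference_probe_ids]
    baseline = ref_counts[list(reference_samples)].median(axis=1)
    if (baseline <= 0).any():
        zero = baseline.index[baseline <= 0].tolist()
        raise ValueError(f"reference probes with zero baseline: {zero[:5]}")
    scale = ref_counts.div(baseline, axis=0).median(axis=0)
    rel = kept / scale
    # step 2: compare against the reference samples
    ref_median = rel[list(reference_samples)].median(axis=1)
    if (ref_median <= 0).any():
        zero = ref_median.index[ref_median <= 0].tolist()
        raise ValueError(f"probes with zero median in reference samples: {zero[:5]}")
    dq = rel.div(ref_median, axis=0)

    ref_dq = dq[list(reference_samples)]
    mad = (ref_dq.sub(ref_dq.median(axis=1), axis=0)).abs().median(axis=1)
    probe_noise = 1.4826 * mad

    qc = pd.DataFrame({"control_cv": cv, "qc_pass": cv <= config.control_cv_max})
    return DosageMatrix(
        dq=dq,
        reference_sample_ids=list(reference_samples),
        probe_noise=probe_noise,
        excluded_samples=excluded,
        sample_qc=qc,
    )


def _expected_levels(purity: float) -> dict[str, float]:
    return {
        "biallelic_loss": 1.0 - purity,
        "loss": 1.0 - purity / 2.0,
        "gain": 1.0 + purity / 2.0,
        "multiple_gain": 1.0 + purity,
    }


def _check_purity(purity: float) -> None:
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")


def call_gene_cna(
    dq_values: pd.Series | Sequence[float],
    purity: float,
    config: CallerConfig | None = None,
    probe_noise: pd.Series | Sequence[float] | None = None,
    locus: str = "",
) -> CnaCall:
    """Classify one gene in one sample from its per-probe dosage quotients.

    Probes must be given in genomic order. The call uses the longest run of
    consecutive aberrant probes; a gene whose aberrant probes disagree in
    direction yields a ``normal`` call carrying a ``direction_conflict``
    flag. Deviations matching a purity-expected clonal level within
    ``level_tolerance`` are clonal; deviations outside the normal band but
    short of the monoallelic-loss (for losses) or one-copy-gain (for gains)
    level are subclonal.
    """
    config = config or CallerConfig()
    _check_purity(purity)
    dq = np.asarray(pd.Series(dq_values).to_numpy(), dtype=float)
    if dq.size == 0:
        raise ValueError("no probes supplied")
    if probe_noise is None:
        noise = np.zeros_like(dq)
    else:
        noise = np.asarray(pd.Series(probe_noise).to_numpy(), dtype=float)

    band = np.maximum(config.normal_band_floor, config.robust_sd_mult * noise)
    dev = dq - 1.0
    if dq.size == 1:
        thr = max(config.single_probe_threshold, config.robust_sd_mult * float(noise[0]))
        aberrant = np.abs(dev) > thr
    else:
        aberrant = np.abs(dev) > band
    if not aberrant.any():
        return CnaCall(locus, CnaState.NORMAL, Clonality.CLONAL, 0, float(dq.mean()))

    directions = np.sign(dev[aberrant])
    if len(set(directions)) > 1:
        return CnaCall(
            locus, CnaState.NORMAL, Clonality.CLONAL, 0, float(dq.mean()),
            flags=("direction_conflict",),
        )

    # longest run of consecutive aberrant probes
    best_start = best_len = 0
    run_start = None
    for i, a in enumerate(np.append(aberrant, False)):
        if a and run_start is None:
            run_start = i
        elif not a and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if dq.size >= 2 and best_len < config.min_consecutive:
        return CnaCall(
            locus, CnaState.NORMAL, Clonality.CLONAL, 0, float(dq.mean()),
            flags=("isolated_probe",),
        )
    run = slice(best_start, best_start + best_len)
    mean_dq = float(dq[run].mean())
    n_support = int(best_len)

    levels = _expected_levels(purity)
    tol = config.level_tolerance
    if mean_dq < 1.0:
        if mean_dq > levels["loss"] + tol:
            state, clonality = CnaState.LOSS, Clonality.SUBCLONAL
        elif abs(mean_dq - levels["loss"]) <= abs(mean_dq - levels["biallelic_loss"]):
            state, clonality = CnaState.LOSS, Clonality.CLONAL
        else:
            state, clonality = CnaState.BIALLELIC_LOSS, Clonality.CLONAL
    else:
        if mean_dq < levels["gain"] - tol:
            state, clonality = CnaState.GAIN, Clonality.SUBCLONAL
        elif mean_dq > (levels["gain"] + levels["multiple_gain"]) / 2.0:
            state, clonality = CnaState.MULTIPLE_GAIN, Clonality.CLONAL
        else:
            state, clonality = CnaState.GAIN, Clonality.CLONAL
    return CnaCall(locus, state, clonality, n_support, mean_dq)


def call_sample(
    dosage: DosageMatrix,
    panel: ProbePanel,
    sample_id: str,
    purity: float,
    config: CallerConfig | None = None,
) -> list[CnaCall]:
    """Gene-level calls for every target gene of one sample."""
    config = config or CallerConfig()
    col = dosage.dq[sample_id]
    calls = []
    for gene in panel.target_genes:
        probes = panel.probes_for_gene(gene)["probe_id"]
        calls.append(
            call_gene_cna(
                col[probes], purity, config,
                probe_noise=dosage.probe_noise[probes], locus=gene,
            )
        )
    return calls


def call_cohort(
    dosage: DosageMatrix,
    panel: ProbePanel,
    purities: Mapping[str, float],
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Tidy table of gene calls for every (non-reference) sample.

    Columns: ``sample_id locus state clonality n_probes mean_dq flags``.
    """
    rows = []
    for sample in dosage.dq.columns:
        if sample in dosage.reference_sample_ids:
            continue
        for c in call_sample(dosage, panel, sample, purities[sample], config):
            rows.append(
                dict(sample_id=sample, locus=c.locus, state=c.state.value,
                     clonality=c.clonality.value, n_probes=c.n_probes_supporting,
                     mean_dq=c.mean_dq, flags=";".join(c.flags))
            )
    return pd.DataFrame(rows)


def ikzf1_deletion_pattern(
    deleted: Mapping[str, bool] | Sequence[bool],
) -> str | list[str]:
    """Label the *IKZF1* deletion pattern from per-probe deleted flags.

    ``deleted`` maps each probe label of :data:`IKZF1_PROBE_ORDER` (two
    upstream probes then exons 1-8) to whether it is deleted, or is a
    same-length boolean sequence in that order. Returns ``"none"``, a single
    interval label such as ``"ex4-7"`` or ``"upstream+ex1-8"``, or — for
    non-contiguous deletions — the list of interval labels.
    """
    if isinstance(deleted, Mapping):
        missing = [p for p in IKZF1_PROBE_ORDER if p not in deleted]
        if missing:
            raise ValueError(f"missing IKZF1 probes: {missing}")
        flags = [bool(deleted[p]) for p in IKZF1_PROBE_ORDER]
    else:
        flags = [bool(x) for x in deleted]
        if len(flags) != len(IKZF1_PROBE_ORDER):
            raise ValueError(
                f"expected {len(IKZF1_PROBE_ORDER)} flags, got {len(flags)}"
            )

    intervals: list[str] = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        labels = IKZF1_PROBE_ORDER[i : j + 1]
        exons = [int(l[2:]) for l in labels if l.startswith("ex")]
        has_upstream = any(l.startswith("up") for l in labels)
        if exons:
            span = f"ex{exons[0]}" if exons[0] == exons[-1] else f"ex{exons[0]}-{exons[-1]}"
            intervals.append(f"upstream+{span}" if has_upstream else span)
        else:
            intervals.append("upstream")
        i = j + 1
    if not intervals:
        return "none"
    if len(intervals) == 1:
        return intervals[0]
    return intervals


def arm_dosage(dosage: DosageMatrix, panel: ProbePanel, sample_id: str) -> dict[str, float]:
    """Per-arm dosage quotients (keys like ``"1p"``) of one sample."""
    arms = panel.arm_probes()
    col = dosage.dq[sample_id]
    return {
        f"{row.chrom}{row.arm}": float(col[row.probe_id])
        for row in arms.itertuples()
    }


def digital_karyotype(
    arm_dq: Mapping[str, float],
    purity: float,
    config: CallerConfig | None = None,
) -> KaryotypeEstimate:
    """Estimate per-chromosome copy numbers and the modal chromosome number.

    Arm DQs are purity-corrected (``cn = 2 (dq - (1 - p)) / p``) and rounded
    to the nearest integer copy number. A chromosome whose two arms deviate
    in opposite directions is flagged ``structural`` and does not change the
    modal number; when both arms deviate the same way the smaller deviation
    wins (whole-chromosome changes must involve both arms). The modal number
    is the sum over chromosomes 1-22 and X (Y is not modelled); a modal
    number of 51-67 is high-hyperdiploid and >= 68 near-triploid.
    """
    config = config or CallerConfig()
    _check_purity(purity)

    def arm_cn(dq: float) -> int:
        if abs(dq - 1.0) <= config.normal_band_floor:
            return 2
        cn = 2.0 * (dq - (1.0 - purity)) / purity
        return max(0, int(round(cn)))

    copy_numbers: dict[str, int] = {}
    structural: list[str] = []
    for chrom in CHROMOSOMES:
        arms = ("q",) if chrom in ACROCENTRIC else ("p", "q")
        cns = []
        for arm in arms:
            key = f"{chrom}{arm}"
            if key not in arm_dq:
                raise ValueError(f"missing arm dosage quotient for {key}")
            cns.append(arm_cn(arm_dq[key]))
        if len(cns) == 1 or cns[0] == cns[1]:
            cn = cns[0]
        else:
            d0, d1 = cns[0] - 2, cns[1] - 2
            if d0 * d1 < 0:
                structural.append(chrom)
                cn = 2
            else:
                # same direction, different magnitude: conservative call
                cn = cns[0] if abs(d0) <= abs(d1) else cns[1]
                if d0 == 0 or d1 == 0:
                    structural.append(chrom)
        copy_numbers[chrom] = cn

    modal = int(sum(copy_numbers.values()))
    if 51 <= modal <= 67:
        ploidy = PloidyClass.HIGH_HYPERDIPLOID
    elif modal >= 68:
        ploidy = PloidyClass.NEAR_TRIPLOID
    elif modal < 46:
        ploidy = PloidyClass.OTHER
    else:
        ploidy = PloidyClass.NON_HYPERDIPLOID
    return KaryotypeEstimate(
        copy_numbers=copy_numbers,
        modal_number=modal,
        ploidy_class=ploidy,
        structural=tuple(structural),
    )
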