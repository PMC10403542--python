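"""Synthetic B-ALL cohort generation.

Emulates the statistical structure of a pediatric B-cell precursor ALL
discovery cohort: cytogenetic subtypes with realistic frequencies,
subtype-conditional lesion probabilities (so the known co-segregation
patterns — e.g. *ETV6* loss with ETV6-RUNX1 fusion, *IKZF1* loss with
BCR-ABL1 — are reproduced), blast purity bounded on [0.29, 0.99] with mean
near 0.79, exponential event times whose hazards depend on the patient's
planted risk group, and negative-binomial probe read counts over the
default panel.

Everything is reproducible from ``SimulationConfig.seed``; the read-count
generator uses an independent substream of the same seed so cohorts and
counts can be generated in either order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import CnaCall, CnaState, Clonality, KaryotypeEstimate, PloidyClass
from .classify import classify_personall
from .panel import ACROCENTRIC, CHROMOSOMES, IKZF1_PROBE_ORDER, ProbePanel, build_default_panel
from .profiles import LesionProfile, PatientRecord, build_profile
from .scoring import ScoreTable

__all__ = [
    "SimulationConfig",
    "PatientTruth",
    "SyntheticTruth",
    "generate_cohort",
    "generate_probe_counts",
    "planted_hr_config",
]

# Exponential hazards (per month) reproducing the reported 5-year EFS of the
# four risk groups: 96.3%, 87.2%, 67.4% and 39.0% at 60 months.
DEFAULT_GROUP_HAZARDS: dict[str, float] = {
    "excellent": -math.log(0.963) / 60.0,
    "good": -math.log(0.872) / 60.0,
    "high": -math.log(0.674) / 60.0,
    "ultra_poor": -math.log(0.390) / 60.0,
}

#: Cohort composition: high-hyperdiploid ~32% and ETV6-RUNX1 ~25% dominate;
#: adverse fusion genotypes are rare.
DEFAULT_SUBTYPE_FREQS: dict[str, float] = {
    "HHD": 0.315,
    "ETV6-RUNX1": 0.25,
    "BCR-ABL1": 0.03,
    "KMT2A-r": 0.02,
    "TCF3-PBX1": 0.03,
    "iAMP21": 0.03,
    "Ph-like": 0.05,
    "B-other": 0.275,
}

# Subtype-conditional Bernoulli probabilities per gene lesion. Keys besides
# "default" override the probability within the named subtype, encoding the
# published co-segregation structure.
DEFAULT_LESION_PROBS: dict[str, dict[str, float]] = {
    "VPREB1:loss": {"default": 0.25, "ETV6-RUNX1": 0.55, "HHD": 0.20},
    "CDKN2A/B:loss": {"default": 0.30, "HHD": 0.12, "iAMP21": 0.60, "Ph-like": 0.40},
    "ETV6:loss": {"default": 0.12, "ETV6-RUNX1": 0.65, "HHD": 0.06},
    "PAX5:loss": {"default": 0.18, "HHD": 0.08},
    "IKZF1:loss": {"default": 0.12, "BCR-ABL1": 0.60, "Ph-like": 0.45,
                   "ETV6-RUNX1": 0.03, "HHD": 0.04},
    "MLLT3:loss": {"default": 0.10, "BCR-ABL1": 0.35},
    "PAR1:loss": {"default": 0.06, "Ph-like": 0.30},
    "TBL1XR1:loss": {"default": 0.03, "ETV6-RUNX1": 0.20},
    "BTG1:loss": {"default": 0.06, "ETV6-RUNX1": 0.10},
    "RB1:loss": {"default": 0.05, "iAMP21": 0.50},
    "BTLA/CD200:loss": {"default": 0.05, "BCR-ABL1": 0.30},
    "CASP8AP2:loss": {"default": 0.06},
    "TP53:loss": {"default": 0.04},
    "NR3C1:loss": {"default": 0.03},
    "EBF1:loss": {"default": 0.02},
    "ERG:loss": {"default": 0.015},
    "RUNX1:gain": {"default": 0.02, "iAMP21": 1.0, "HHD": 0.10},
}

#: Fraction of gene lesions that are biallelic (losses) / multi-copy (gains).
DEFAULT_BIALLELIC_PROBS: dict[str, float] = {
    "VPREB1:loss": 0.21,
    "CDKN2A/B:loss": 0.39,
    "RUNX1:gain": 0.48,
}

#: The generator's planted weighting of lesions; defines each patient's true
#: risk group and therefore its hazard. Mirrors the intended design: strong
#: favorable markers (ETV6-RUNX1 fusion, high-hyperdiploidy with double
#: trisomy 4+6) reach the excellent threshold alone or pairwise, adverse
#: fusions and IKZF1 lesions pull toward ultra-poor.
DEFAULT_PLANTED_SCORES: dict[str, int] = {
    "ETV6-RUNX1": 4,
    "HHD": 2,
    "DT4_6": 2,
    "ETV6:loss": 1,
    "BCR-ABL1": -4,
    "Ph-like": -3,
    "KMT2A-r": -3,
    "iAMP21": -3,
    "IKZF1plus": -3,
    "IKZF1:loss": -2,
    "CDKN2A/B:loss": -1,
    "TP53:loss": -2,
    "RB1:loss": -1,
}

# Chromosome-gain propensities within the high-hyperdiploid subtype
# (favouring 21, X, 14, 6, 18, 17, 4 and 10, with 4 and 6 common enough for
# the double trisomy to be frequent).
_HHD_GAIN_WEIGHTS: dict[str, float] = {
    "21": 1.0, "X": 0.9, "14": 0.85, "6": 0.8, "18": 0.75, "17": 0.7,
    "4": 0.8, "10": 0.65, "8": 0.2, "5": 0.1, "12": 0.1, "2": 0.08,
    "3": 0.08, "9": 0.08, "16": 0.08, "22": 0.12, "11": 0.05, "13": 0.1,
}

#: Whole-gene and partial IKZF1 deletion patterns with sampling weights.
_IKZF1_PATTERNS: dict[str, float] = {
    "ex4-7": 0.35,
    "ex1-7": 0.20,
    "upstream+ex1-8": 0.25,
    "ex2-7": 0.10,
    "ex1-2": 0.10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort and read-count generators."""

    n_patients: int = 260
    seed: int = 0
    subtype_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_FREQS))
    lesion_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LESION_PROBS.items()})
    biallelic_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIALLELIC_PROBS))
    planted_scores: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_SCORES))
    purity_range: tuple[float, float] = (0.29, 0.99)
    purity_beta: tuple[float, float] = (5.0, 2.0)  # mean 5/7 of the range -> ~0.79
    group_hazards: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_HAZARDS))
    lesion_hazard_ratios: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.004
    censor_rate: float = 0.004
    admin_censor_months: float = 60.0
    weibull_shape: float = 1.0  # 1.0 = exponential event times
    subclonal_prob: float = 0.08
    subclonal_fraction_range: tuple[float, float] = (0.3, 0.7)
    depth: float = 1000.0
    dispersion: float | None = 0.02  # NB overdispersion; 0 Poisson; None exact
    probe_efficiency_sd: float = 0.3
    sample_depth_sd: float = 0.2
    n_reference_samples: int = 8

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        total = sum(self.subtype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype frequencies must sum to 1 (got {total})")
        for lesion, probs in self.lesion_probs.items():
            if "default" not in probs:
                raise ValueError(f"{lesion}: lesion probabilities need a 'default'")
            for k, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{lesion}[{k}]: probability {p} outside [0, 1]")
        for g, h in self.group_hazards.items():
            if h <= 0:
                raise ValueError(f"hazard for group {g!r} must be > 0")
        for l, hr in self.lesion_hazard_ratios.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {l!r} must be > 0")
        lo, hi = self.purity_range
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("purity range must satisfy 0 < low < high <= 1")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    subtype: str
    purity: float
    copy_numbers: dict[str, int]
    gene_states: dict[str, tuple[CnaState, float]]  # gene -> (state, cell fraction)
    ikzf1_pattern: str
    lesions: frozenset[str]
    true_score: int
    true_group: str
    event_time: float  # pre-censoring


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    patients: list[PatientTruth]


_FUSION_SUBTYPES = {"ETV6-RUNX1", "BCR-ABL1", "TCF3-PBX1", "KMT2A-r", "iAMP21", "Ph-like"}

_STATE_CN = {
    CnaState.NORMAL: 2, CnaState.LOSS: 1, CnaState.BIALLELIC_LOSS: 0,
    CnaState.GAIN: 3, CnaState.MULTIPLE_GAIN: 4,
}

# age weights: geometric-like decay gives the typical young-skewed B-ALL
# age distribution (median ~5 years)
_AGES = np.arange(1, 18)
_AGE_W = 0.85 ** _AGES
_AGE_W = _AGE_W / _AGE_W.sum()


def _sample_karyotype(subtype: str, rng: np.random.Generator) -> dict[str, int]:
    cn = {c: 2 for c in CHROMOSOMES}
    if subtype == "HHD":
        # 5-9 gained chromosomes (modal 51-57). Beyond ~10 simultaneous
        # gains a median-based normalization baseline starts to collapse
        # onto the gained level; see the methods note.
        n_gains = int(rng.integers(5, 10))
        chroms = list(_HHD_GAIN_WEIGHTS)
        w = np.array([_HHD_GAIN_WEIGHTS[c] for c in chroms])
        picked = rng.choice(chroms, size=n_gains, replace=False, p=w / w.sum())
        for c in picked:
            cn[c] = 3
            if c in ("21", "X", "14", "18") and rng.random() < 0.2:
                cn[c] = 4
    elif rng.random() < 0.03:
        cn["21"] = 3  # occasional isolated trisomy outside HHD
    return cn


def _true_karyotype_estimate(copy_numbers: Mapping[str, int]) -> KaryotypeEstimate:
    modal = int(sum(copy_numbers.values()))
    if 51 <= modal <= 67:
        ploidy = PloidyClass.HIGH_HYPERDIPLOID
    elif modal >= 68:
        ploidy = PloidyClass.NEAR_TRIPLOID
    elif modal < 46:
        ploidy = PloidyClass.OTHER
    else:
        ploidy = PloidyClass.NON_HYPERDIPLOID
    return KaryotypeEstimate(dict(copy_numbers), modal, ploidy)


def _truth_calls(
    truth: PatientTruth, genes: Sequence[str]
) -> list[CnaCall]:
    """Noise-free CnaCall objects matching the planted gene states."""
    calls = []
    for gene in genes:
        state, cf = truth.gene_states.get(gene, (CnaState.NORMAL, 1.0))
        clonality = Clonality.SUBCLONAL if (state is not CnaState.NORMAL and cf < 1.0) else Clonality.CLONAL
        p = truth.purity
        level = 1.0 + p * cf * (_STATE_CN[state] - 2) / 2.0
        calls.append(CnaCall(gene, state, clonality, 2, level))
    return calls


def _planted_score(lesions: frozenset[str], planted: Mapping[str, int]) -> int:
    s = 0
    superseded = {"IKZF1:loss"} if "IKZF1plus" in lesions and "IKZF1plus" in planted else set()
    for lesion, w in planted.items():
        if lesion in lesions and lesion not in superseded:
            s += w
    return s


def generate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[list[PatientRecord], list[LesionProfile], SyntheticTruth]:
    """Sample a full synthetic cohort (records, lesion profiles, truth).

    Subtype first, then subtype-conditional lesions, then purity and
    outcome. Event times are Weibull (exponential by default) with the
    hazard of the patient's planted risk group, or — when
    ``lesion_hazard_ratios`` is set — a proportional-hazards model
    ``baseline_hazard * prod(HR_l^carrier)``. Censoring is an independent
    exponential plus an administrative cutoff.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    subtypes = list(config.subtype_freqs)
    st_p = np.array([config.subtype_freqs[s] for s in subtypes])
    panel_genes = sorted({l.split(":")[0] for l in config.lesion_probs} | {"ERG", "PAX5", "PAR1", "CDKN2A/B", "IKZF1"})

    records, profiles, truths = [], [], []
    lo, hi = config.purity_range
    a, b = config.purity_beta
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        subtype = str(rng.choice(subtypes, p=st_p))
        cn = _sample_karyotype(subtype, rng)
        purity = float(lo + (hi - lo) * rng.beta(a, b))

        gene_states: dict[str, tuple[CnaState, float]] = {}
        for lesion, probs in config.lesion_probs.items():
            gene, kind = lesion.split(":")
            p = probs.get(subtype, probs["default"])
            if rng.random() >= p:
                continue
            if kind == "loss":
                state = CnaState.LOSS
                if rng.random() < config.biallelic_probs.get(lesion, 0.0):
                    state = CnaState.BIALLELIC_LOSS
            else:
                state = CnaState.GAIN
                if rng.random() < config.biallelic_probs.get(lesion, 0.0):
                    state = CnaState.MULTIPLE_GAIN
            cf = 1.0
            if state in (CnaState.LOSS, CnaState.GAIN) and rng.random() < config.subclonal_prob:
                cf = float(rng.uniform(*config.subclonal_fraction_range))
            gene_states[gene] = (state, cf)

        ikzf1_pattern = "none"
        if "IKZF1" in gene_states:
            pats = list(_IKZF1_PATTERNS)
            pw = np.array([_IKZF1_PATTERNS[p_] for p_ in pats])
            ikzf1_pattern = str(rng.choice(pats, p=pw / pw.sum()))

        fusions = frozenset(
            {subtype if subtype != "Ph-like" else "Ph-like-marker"}
            if subtype in _FUSION_SUBTYPES else set()
        )
        age = int(rng.choice(_AGES, p=_AGE_W))
        sex = "M" if rng.random() < 1.43 / 2.43 else "F"

        # outcome placeholder; filled after the profile determines the group
        record = PatientRecord(
            patient_id=pid, age_years=age, sex=sex, purity=purity,
            fusion_markers=fusions, efs_months=0.0, event=0,
        )
        truth = PatientTruth(
            patient_id=pid, subtype=subtype, purity=purity, copy_numbers=cn,
            gene_states=gene_states, ikzf1_pattern=ikzf1_pattern,
            lesions=frozenset(), true_score=0, true_group="", event_time=0.0,
        )
        profile = build_profile(
            record, _truth_calls(truth, panel_genes), _true_karyotype_estimate(cn)
        )
        truth.lesions = profile.lesions
        truth.true_score = _planted_score(profile.lesions, config.planted_scores)
        truth.true_group = classify_personall(truth.true_score).value

        if config.lesion_hazard_ratios:
            log_hr = sum(
                math.log(hr)
                for l, hr in config.lesion_hazard_ratios.items()
                if l in profile.lesions
            )
            hazard = config.baseline_hazard * math.exp(log_hr)
        else:
            hazard = config.group_hazards[truth.true_group]
        # Weibull with scale such that the marginal hazard matches at shape 1
        u = rng.random()
        t_event = (-math.log(1.0 - u)) ** (1.0 / config.weibull_shape) / hazard
        t_cens = rng.exponential(1.0 / config.censor_rate) if config.censor_rate > 0 else math.inf
        t_admin = config.admin_censor_months
        efs = min(t_event, t_cens, t_admin)
        event = int(t_event <= min(t_cens, t_admin))
        truth.event_time = t_event

        record = replace(record, efs_months=float(efs), event=event)
        records.append(record)
        profiles.append(
            LesionProfile(
                patient_id=pid, lesions=profile.lesions,
                assessed_loci=profile.assessed_loci, subtype=profile.subtype,
                ikzf_status=profile.ikzf_status,
            )
        )
        truths.append(truth)

    return records, profiles, SyntheticTruth(config=config, patients=truths)


def _ikzf1_deleted_labels(pattern: str) -> set[str]:
    if pattern == "none":
        return set()
    labels: set[str] = set()
    for part in pattern.split("+"):
        if part == "upstream":
            labels |= {"up4kb", "up2kb"}
        else:
            span = part[2:]
            if "-" in span:
                a_, b_ = span.split("-")
                labels |= {f"ex{k}" for k in range(int(a_), int(b_) + 1)}
            else:
                labels.add(f"ex{span}")
    return labels


def generate_probe_counts(
    truth: SyntheticTruth,
    panel: ProbePanel | None = None,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Probe read counts for all patients plus pure-diploid reference samples.

    Expected count of probe j in sample i is
    ``depth * efficiency_j * depth_factor_i * level_ij / 2`` where
    ``level`` is the purity-mixed copy level of the probe's locus.
    Counts are negative binomial with the configured dispersion (Poisson at
    0; exact rounded expectations when ``dispersion`` is None). Returns the
    counts (probes x samples) and the reference sample ids.
    """
    panel = panel or build_default_panel()
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])

    # probe efficiencies shared across samples (cancelled by normalization)
    eff = np.exp(rng.normal(0.0, config.probe_efficiency_sd, size=len(panel.table))) \
        if config.probe_efficiency_sd > 0 else np.ones(len(panel.table))
    eff_by_probe = dict(zip(panel.table["probe_id"], eff))

    ref_ids = [f"REF{i + 1:02d}" for i in range(config.n_reference_samples)]
    sample_ids = ref_ids + [p.patient_id for p in truth.patients]
    by_id = {p.patient_id: p for p in truth.patients}

    def probe_level(row, pt: PatientTruth | None) -> float:
        if pt is None:
            return 2.0
        if row.role == "control":
            return 2.0
        if row.role == "reference":
            cn = pt.copy_numbers.get(row.chrom, 2)
            return pt.purity * cn + (1.0 - pt.purity) * 2.0
        gene = row.gene
        state, cf = pt.gene_states.get(gene, (CnaState.NORMAL, 1.0))
        cn = _STATE_CN[state]
        if gene == "IKZF1":
            deleted = _ikzf1_deleted_labels(pt.ikzf1_pattern)
            cn = _STATE_CN[state] if row.exon in deleted else 2
        blast_cn = cf * cn + (1.0 - cf) * 2.0
        return pt.purity * blast_cn + (1.0 - pt.purity) * 2.0

    cols = {}
    for sid in sample_ids:
        pt = by_id.get(sid)
        depth_factor = (
            float(np.exp(rng.normal(0.0, config.sample_depth_sd)))
            if config.sample_depth_sd > 0 else 1.0
        )
        mean = np.array([
            config.depth * eff_by_probe[row.probe_id] * depth_factor
            * probe_level(row, pt) / 2.0
            for row in panel.table.itertuples()
        ])
        if config.dispersion is None:
            counts = np.round(mean).astype(int)
        elif config.dispersion == 0:
            counts = rng.poisson(mean)
        else:
            alpha = config.dispersion
            n_param = 1.0 / alpha
            p_param = 1.0 / (1.0 + alpha * mean)
            counts = rng.negative_binomial(n_param, p_param)
        cols[sid] = counts
    counts = pd.DataFrame(cols, index=panel.table["probe_id"].tolist())
    return counts, ref_ids


def planted_hr_config(
    n_patients: int,
    seed: int,
    lesion_freqs: Mapping[str, float],
    hazard_ratios: Mapping[str, float],
    baseline_hazard: float = 0.008,
    censor_rate: float = 0.004,
) -> SimulationConfig:
    """A minimal single-subtype config with lesions at fixed frequencies and
    planted proportional hazards; used for parameter-recovery studies."""
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        subtype_freqs={"B-other": 1.0},
        lesion_probs={l: {"default": f} for l, f in lesion_freqs.items()},
        biallelic_probs={},
        planted_scores={},
        subclonal_prob=0.0,
        lesion_hazard_ratios=dict(hazard_ratios),
        baseline_hazard=baseline_hazard,
        censor_rate=censor_rate,
    )
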