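# Methods

## Overview

`personall` implements a personalized genetic risk-assessment stack for
pediatric B-cell precursor acute lymphoblastic leukemia (B-ALL). It has
five analytic layers:

1. **Copy-number calling** from MLPA-with-sequencing-readout ("digitalMLPA"
   style) probe read counts: two-step normalization into dosage quotients
   (DQ), then purity-aware gene- and arm-level calls.
2. **Profile building**: per-patient lesion sets merging gene CNAs, the
   digital karyotype, externally supplied fusion/cytogenetic markers, and
   composite genotypes (IKZF1plus, double trisomy 4+6, high-hyperdiploidy).
3. **Score derivation**: univariate Cox proportional-hazards fits per
   lesion, a frequency/hazard-ratio selection filter, and signed integer
   weights.
4. **Classification**: the cumulative-score four-group classifier
   (excellent / good / high / ultra-poor) and the cytogenetics-aware
   three-group IKAROS classifier.
5. **Survival and co-segregation statistics**: Kaplan-Meier with Greenwood
   standard errors, k-group log-rank, Benjamini-Hochberg / Bonferroni
   adjustment, pairwise Fisher exact co-occurrence testing.

A synthetic-cohort generator makes the whole stack testable without
patient data.

## Dosage quotients and the purity mixture model

A specimen with blast purity `p` (leukemic-cell fraction, assessed by flow
cytometry in practice) containing a clonal aberration of copy number `c`
at a locus yields an expected DQ of `(p·c + (1−p)·2) / 2`, i.e.

| state              | expected DQ |
|--------------------|-------------|
| biallelic loss     | 1 − p       |
| monoallelic loss   | 1 − p/2     |
| copy-neutral       | 1.0         |
| one-copy gain      | 1 + p/2     |
| multiple gain      | ≥ 1 + p     |

A lesion carried by only a fraction `f` of the blasts (subclonal)
interpolates between 1.0 and the clonal level with weight `p·f`. The
caller uses exactly this geometry: a probe is *aberrant* when its DQ
leaves the normal band `|DQ − 1| > max(0.15, 3 × robust SD)` (the robust
SD is 1.4826 × MAD of that probe's DQ across reference samples); a run of
≥ 2 consecutive aberrant probes (single-probe genes need `|DQ − 1| > 0.3`)
is matched to the nearest purity-expected level within a tolerance of
0.10 DQ units, ties resolving to the less extreme state. A deviation
outside the band but short of the monoallelic-loss level (for losses) or
the one-copy-gain level (for gains) is called **subclonal**. Probes of
one gene deviating in opposite directions produce a flagged `normal`
call. Biallelic-loss calls always satisfy `mean DQ < 1 − p/2` by
construction.

### Normalization

Step 1 (intra-sample): each sample's scaling factor is the **median over
reference probes of count / probe-baseline**, where a probe's baseline is
its median count across the reference samples. Step 2 (inter-sample):
each relative count is divided by the median of the matching values
across the reference samples. Taking the step-1 median on the ratio scale
rather than on raw counts makes the factor invariant to per-probe
efficiency differences; this matters because in a hyperdiploid genome up
to a third of the karyotyping reference arms are genuinely gained, and a
raw-count median would slide to a different efficiency quantile and shift
the entire sample's baseline. With equal probe efficiencies the two forms
coincide. Control probes never enter normalization; they provide a
per-sample QC gate (CV of efficiency-corrected control signals ≤ 0.25).

### Digital karyotype

Arm-level DQs are purity-corrected (`cn = 2(DQ − (1−p))/p`, rounded) and
combined per chromosome; arms deviating in opposite directions flag the
chromosome `structural` and leave the modal count unchanged. The modal
chromosome number sums chromosomes 1-22 and X (Y is not modelled;
baseline 46). Modal 51-67 is high-hyperdiploid (HHD), ≥ 68 near-triploid,
< 46 "other".

## Composite genotypes

* **IKZF1plus**: IKZF1 deletion co-occurring with CDKN2A/B, PAX5 or PAR1
  deletion in the absence of ERG deletion. Requires calls (possibly
  normal) for all five loci; assigning the status with any of them
  unassessed is an error.
* **DT4_6**: copy number ≥ 3 on both chromosomes 4 and 6 (further combos
  configurable).
* **Subtype**: one label per patient with precedence BCR-ABL1 > KMT2A-r >
  Ph-like > TCF3-PBX1 > iAMP21 > ETV6-RUNX1 > HHD > B-other. Adverse
  fusions dominate clinical assignment, which is why they outrank the
  favorable genotypes; the remainder is B-other.
* **IKZF1 deletion patterns**: exon-resolution labels over two upstream
  probes and exons 1-8 ("ex4-7", "upstream+ex1-8", ...); non-contiguous
  deletions return the list of intervals.

## Score derivation

Event-free survival (EFS, months from treatment start to relapse, second
malignancy or disease-related death) is truncated at 60 months before
fitting: later events are censored at 60, so derivation reflects 5-year
outcome only.

Per candidate lesion (every token observed in ≥ 1 profile, composites
included as first-class predicates), a univariate Cox model
`h(t|x) = h0(t)·exp(βx)` is fitted to the binary carrier indicator by
Newton-Raphson on the partial likelihood (convergence `|Δβ| < 1e-8`, step
halving, Wald SE from the observed information). Ties are handled by the
Efron approximation by default; Breslow and — for binary covariates — the
exact discrete likelihood are available and coincide with Efron when no
event times are tied. Monotone likelihoods (complete separation) are
detected, capped at `|β| ≤ 10`, flagged, and **excluded from scoring**: a
lesion whose carriers had no events in a few-hundred-patient cohort has
no usable effect size.

Selection keeps lesions with cohort frequency `> 1.5%` (strict) and
hazard ratio `> 1.5` (strict) or `≤ 0.66` (inclusive); the frequency
denominator is the full cohort. The default weight is
`magnitude = clamp(round(|ln HR| / ln 1.5), 1, 4)`, signed positive for
protective (HR ≤ 0.66) and negative for adverse (HR > 1.5) lesions, so
the maximal per-lesion weight (4) alone reaches the excellent threshold.
A hand-set table (e.g. a published supplementary weighting) can be loaded
from JSON instead; the two are interchangeable everywhere.

**Exclusion groups** prevent double counting in the cumulative sum: within
each ordered group only the first (most specific) matching entry
contributes. Defaults: IKZF1plus ⊃ IKZF1 loss; biallelic loss ⊃ loss and
multiple gain ⊃ gain per gene; DT4_6 ⊃ +4/+6; HHD ⊃ each individual
whole-chromosome gain. All are overridable via the score-table JSON.

## Classification

* **PersonALL**: cumulative score S thresholds — excellent S ≥ 4, good
  0 ≤ S ≤ 3, high −3 ≤ S ≤ −1, ultra-poor S ≤ −4. The published ranges
  overlap at −4 ("−1 to −4" vs "≤ −4"); −4 is resolved to ultra-poor,
  reading the ultra-poor bound as inclusive and keeping the ranges a
  partition of the integers.
* **IKAROS**: subtypes map to cytogenetic risk classes (good =
  {ETV6-RUNX1, HHD}; poor = {BCR-ABL1, Ph-like, KMT2A-r, iAMP21};
  intermediate = rest), and a total (risk class × IKZF1 status) matrix
  yields IKAROS-low/-medium/-high. The default matrix (normal → low
  everywhere; del → low in the good class, else medium; plus → medium in
  the good class, else high) encodes the intended escalation and is fully
  config-overridable.

## Survival and co-segregation statistics

Kaplan-Meier uses the product-limit estimator with events-first handling
at tied times and Greenwood standard errors; the 5-year EFS is the step
value at or before 60 months. The k-group log-rank statistic uses the
hypergeometric covariance of observed-minus-expected event counts with a
pseudo-inverse over k−1 groups. Benjamini-Hochberg (monotone step-up) and
Bonferroni adjustments delegate to statsmodels, with a declared-`m`
variant for when more comparisons were made than p-values adjusted.

Pairwise co-segregation uses the two-sided Fisher exact test (sum of
hypergeometric probabilities not exceeding the observed table's —
scipy's convention). A pair is labelled co-occurring (OR > 1) or mutually
exclusive (OR < 1) only when significant after BH; the displayed odds
ratio applies the Haldane-Anscombe 0.5 correction when a cell is empty,
the p-value never does. Lesions carried by all or no patients are skipped
with a log entry.

## Synthetic cohorts

The generator emulates a 260-patient discovery-style cohort:

* **Subtypes** at realistic frequencies (HHD 31.5%, ETV6-RUNX1 25%,
  B-other 27.5%, Ph-like 5%, BCR-ABL1/TCF3-PBX1/iAMP21 3% each,
  KMT2A-r 2%).
* **Lesions** as subtype-conditional Bernoullis reproducing the known
  co-segregation structure (ETV6 loss with ETV6-RUNX1; IKZF1, MLLT3 and
  BTLA/CD200 losses with BCR-ABL1; CDKN2A/B and RB1 losses with iAMP21;
  depleted focal losses within HHD). VPREB1 and CDKN2A/B losses are
  biallelic with probability 0.21/0.39, RUNX1 gains multi-copy with 0.48,
  and 8% of focal lesions are subclonal (cell fraction U(0.3, 0.7)).
* **Purity** `0.29 + 0.70·Beta(5, 2)` — bounded on [0.29, 0.99] with mean
  ≈ 0.79.
* **Karyotype**: HHD patients gain 5-9 chromosomes weighted toward 21, X,
  14, 6, 18, 17, 4 and 10 (occasional tetrasomies of 21/X/14/18), giving
  modal numbers 51-57 with median ≈ 54.
* **Outcome**: exponential event times (Weibull shape configurable) whose
  hazard is either the patient's planted risk-group rate — the rates
  implied by 5-year EFS of 96.3/87.2/67.4/39.0% for
  excellent/good/high/ultra-poor — or, for parameter-recovery studies, a
  proportional-hazards model with per-lesion planted hazard ratios over a
  baseline of 0.004/month. Censoring is an independent exponential
  (0.004/month, ≈ 20% non-administrative censoring) plus an
  administrative cutoff at 60 months. The planted risk group comes from a
  built-in planted score table (strong favorable markers +4/+2+2, adverse
  fusions −3/−4, IKZF1 lesions −2/−3) chosen so that group sizes and the
  favorable/adverse split resemble a real cohort.
* **Read counts**: negative binomial with dispersion 0.02 (variance
  `m + 0.02 m²`; 0 gives Poisson, `null` exact expectations) around
  `depth × probe efficiency × sample depth factor × level/2`, with
  log-normal probe efficiencies (SD 0.3) shared across samples and eight
  pure-diploid reference samples. Everything is reproducible from one
  seed; counts use an independent substream so cohort and counts can be
  generated in either order.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: germline CNVs and probe cross-
hybridization; correlated wave/GC artefacts (probe noise is independent
given the efficiency); interaction of focal lesions with whole-chromosome
gains (gene probes reflect the gene state only); hyperdiploidy beyond 9
gains (above ~10 simultaneous gains a median-style baseline is
unidentifiable without an external ploidy anchor such as a DNA index,
which real workflows use); MRD, treatment effects, and non-proportional
hazards.

## Numerical choices and degenerate inputs

* Medians at both normalization steps; MAD-based robust SD.
* Level matching tolerance 0.10 DQ; ties toward the less extreme state;
  multiple-gain boundary at the midpoint between the one-copy-gain and
  multiple-gain levels.
* Cox: Newton with step halving, 200-iteration cap, grid-free;
  `round-half-away` integer weights.
* Log-rank uses `pinv`, so duplicated/degenerate groups yield statistic 0
  rather than failing.
* Readers reject malformed rows with row/field named; a missing purity
  falls back to the cohort-mean default 0.79 with a warning (disableable).
* Test problem sizes (cohorts of 50-800, 3-50 replicate seeds) were
  chosen as the smallest sizes at which the binomial/SE bounds quoted in
  the tests are meaningful.

## Known limitations

* Exon-level IKZF1 probes are simulated at one probe per exon (the real
  assay has two), so single-probe exon noise suppression is weaker than
  in production panels.
* The score weighting is a reconstruction of "proportional" weighting by
  log-HR bands; published supplementary weights, where available, should
  be loaded verbatim via the score-table JSON.
* Arm-level events feed the karyotype but are not scored as lesions;
  PAR1 is treated as a single region-level locus.
* The IKAROS combination matrix default is a reconstruction; studies
  using a different cytogenetic risk partition must supply their matrix.
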