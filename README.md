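# personall

Personalized genetic risk assessment for pediatric B-cell precursor acute
lymphoblastic leukemia (B-ALL).

Current prognostic classifiers assign a child with B-ALL to a risk group
from a small predefined set of genetic patterns, leaving most patients in
a non-specific collective subgroup. `personall` implements an alternative,
fully combinatorial approach for labs running MLPA-style copy-number
screens alongside conventional cytogenetics:

* **Copy-number calling** from digitalMLPA-style probe read counts:
  two-step normalization into dosage quotients (DQ ≈ 1.0 when copy-
  neutral), blast-purity-aware clonal/subclonal/biallelic calls, exon-
  resolution *IKZF1* deletion patterns, and digital karyotyping
  (modal chromosome number, high-hyperdiploidy, trisomy combinations).
* **Cumulative risk scoring**: every recurrent lesion is fitted in a
  univariate Cox model `h(t|x) = h0(t) e^{βx}` against 5-year event-free
  survival; lesions with frequency > 1.5% and hazard ratio HR > 1.5 or
  ≤ 0.66 receive a signed integer weight
  `±clamp(round(|ln HR|/ln 1.5), 1, 4)`. A patient's score
  `S = Σ w(l)` over their lesions (composites supersede their parts)
  yields four groups: **excellent** (S ≥ 4), **good** (0–3),
  **high** (−3…−1), **ultra-poor** (S ≤ −4).
* **IKAROS classification**: *IKZF1* status (normal / del / plus, where
  *plus* is an *IKZF1* deletion plus a *CDKN2A/B*, *PAX5* or PAR1 deletion
  without *ERG* deletion) crossed with cytogenetic risk classes into
  IKAROS-low/-medium/-high.
* **Survival & co-segregation statistics**: Kaplan–Meier with Greenwood
  SEs, k-group log-rank, BH/Bonferroni correction, pairwise Fisher exact
  co-occurrence/mutual-exclusivity testing.
* **Synthetic cohorts**: subtype-conditional lesion co-segregation, blast
  purity on [0.29, 0.99], group-dependent event hazards and negative-
  binomial read counts, so the entire stack is testable end to end
  without patient data.

## Worked example

```python
import personall as pa

# a discovery-style synthetic cohort of 260 patients
records, profiles, truth = pa.generate_cohort(pa.SimulationConfig(n_patients=260, seed=1))

table, fits = pa.derive_score_table(profiles, records)
risk = pa.classify_cohort(profiles, table)
rec = {r.patient_id: r for r in records}
for group in ("excellent", "good", "high", "ultra_poor"):
    pids = risk.loc[risk["personall_group"] == group, "patient_id"]
    curve = pa.km_estimate([rec[p].efs_months for p in pids],
                           [rec[p].event for p in pids])
    print(f"{group:10s} n={len(pids):3d}  5-year EFS = {100*curve.five_year_efs:.1f}%")
```

prints

```
excellent  n= 87  5-year EFS = 96.3%
good       n=105  5-year EFS = 89.5%
high       n= 42  5-year EFS = 76.9%
ultra_poor n= 26  5-year EFS = 44.8%
```

i.e. the derived score table splits the cohort into four groups whose
observed 5-year event-free survival decreases monotonically from ~96% to
~45% — the favorable groups (ETV6-RUNX1, hyperdiploid with double trisomy
4+6) sit at the top, fusion-adverse and IKZF1plus patients at the bottom.

The `examples/` directory has one short script per capability
(copy-number calling, score derivation and classification, survival and
co-segregation); each prints what it computes and what the numbers mean.

The same pipeline is available as a thin CLI:

```bash
personall simulate --seed 7 --out-dir sim/
personall call-cna --panel sim/panel.tsv --counts sim/counts.tsv \
    --purity sim/purity.tsv --out calls.tsv
personall derive-scores --profiles sim/profiles.tsv --clinical sim/cohort.csv \
    --out scores.json
personall classify --profiles sim/profiles.tsv --score-table scores.json \
    --out risk.csv
personall survival --risk risk.csv --clinical sim/cohort.csv --out km.tsv
personall coseg --profiles sim/profiles.tsv --out coseg.tsv
```

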