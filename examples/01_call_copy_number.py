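"""Copy-number calling from probe read counts.

Simulates a small cohort with shot-noise read counts over the default
panel, normalizes them into dosage quotients, and calls gene-level CNAs
and the digital karyotype for one patient. A dosage quotient of ~1.0 is
copy-neutral; with blast purity p, a clonal monoallelic loss sits near
1 - p/2 and a one-copy gain near 1 + p/2.
"""

import personall as pa
from personall.caller import arm_dosage

cfg = pa.SimulationConfig(n_patients=20, seed=7, dispersion=0)
records, _, truth = pa.generate_cohort(cfg)
panel = pa.build_default_panel()
counts, reference_ids = pa.generate_probe_counts(truth, panel, cfg)

dosage = pa.normalize_read_counts(counts, panel, reference_ids)
print(f"normalized {dosage.dq.shape[0]} probes x {dosage.dq.shape[1]} samples "
      f"({len(reference_ids)} reference samples)")

# pick a patient with at least one lesion
patient = next(r for r, t in zip(records, truth.patients) if t.gene_states)
calls = pa.call_sample(dosage, panel, patient.patient_id, patient.purity)
print(f"\n{patient.patient_id} (blast purity {patient.purity:.2f}):")
for c in calls:
    if c.state is not pa.CnaState.NORMAL:
        print(f"  {c.locus:12s} {c.state.value:15s} {c.clonality.value:9s} "
              f"mean DQ {c.mean_dq:.2f} ({c.n_probes_supporting} probes)")

karyotype = pa.digital_karyotype(
    arm_dosage(dosage, panel, patient.patient_id), patient.purity)
gains = [c for c, n in karyotype.copy_numbers.items() if n >= 3]
print(f"  modal chromosome number {karyotype.modal_number} "
      f"({karyotype.ploidy_class.value}); gained: {'+' + ', +'.join(gains) if gains else 'none'}")
print(f"  truth: {sorted(truth.patients[records.index(patient)].lesions)}")
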