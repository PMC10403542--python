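"""Readers and writers for the tabular and JSON formats of the pipeline.

All readers validate rather than coerce: malformed values raise with the
offending row and field named. All writers emit a deterministic column
order so outputs are diffable.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .caller import CallerConfig, DosageMatrix
from .classify import DEFAULT_IKAROS_MATRIX, IkarosMatrix
from .panel import ProbePanel
from .profiles import (
    FUSION_MARKERS,
    IKZF1_STATUS_LOCI,
    LesionProfile,
    PatientRecord,
    SUBTYPE_PRECEDENCE,
    _ikzf1_status_from,
)
from .scoring import DeriveConfig, ScoreTable
from .simulate import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_panel", "write_panel",
    "read_counts", "write_counts",
    "read_cohort", "write_cohort",
    "read_purity", "write_purity",
    "read_profiles", "write_profiles",
    "read_score_table", "write_score_table",
    "read_caller_config", "read_derive_config",
    "read_ikaros_matrix", "write_ikaros_matrix",
    "read_simulation_config",
    "write_calls", "run_manifest",
]

_COHORT_COLUMNS = ["patient_id", "age", "sex", "purity", "fusions", "efs_months", "event"]

#: Cohort-mean blast purity used (with a warning) when a record omits it.
DEFAULT_PURITY = 0.79


def read_panel(path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "exon": str, "gene": str})
    return ProbePanel(df)


def write_panel(panel: ProbePanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("probe_id").to_csv(path, sep="\t")


def read_cohort(path, default_purity: float | None = DEFAULT_PURITY) -> list[PatientRecord]:
    """Parse the clinical table (CSV).

    Columns: ``patient_id,age,sex,purity,fusions,efs_months,event`` with
    fusions as semicolon-separated tokens. A missing purity falls back to
    ``default_purity`` with a warning (pass ``None`` to forbid that).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "fusions": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    records = []
    seen_ids = set()
    for i, row in enumerate(df.itertuples(), start=2):  # row 1 is the header
        pid = row.patient_id
        if pid in seen_ids:
            raise ValueError(f"row {i}: duplicate patient_id {pid!r}")
        seen_ids.add(pid)
        purity = row.purity
        if pd.isna(purity):
            if default_purity is None:
                raise ValueError(f"row {i}: missing purity for {pid}")
            warnings.warn(
                f"row {i}: missing purity for {pid}; using cohort default "
                f"{default_purity}", stacklevel=2,
            )
            purity = default_purity
        try:
            purity = float(purity)
            efs = float(row.efs_months)
            event = int(row.event)
            age = float(row.age)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-numeric field ({exc})") from None
        if not (0.0 < purity <= 1.0):
            raise ValueError(f"row {i}: purity {purity} outside (0, 1]")
        fus = row.fusions
        markers = frozenset() if pd.isna(fus) or fus == "" else frozenset(
            tok.strip() for tok in str(fus).split(";") if tok.strip()
        )
        try:
            records.append(
                PatientRecord(
                    patient_id=pid, age_years=age, sex=row.sex, purity=purity,
                    fusion_markers=markers, efs_months=efs, event=event,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return records


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    rows = [
        dict(
            patient_id=r.patient_id, age=r.age_years, sex=r.sex, purity=r.purity,
            fusions=";".join(sorted(r.fusion_markers)), efs_months=r.efs_months,
            event=r.event,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def read_purity(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "purity"} <= set(df.columns):
        raise ValueError("purity table needs columns sample_id and purity")
    out = {}
    for i, row in enumerate(df.itertuples(), start=2):
        p = float(row.purity)
        if not (0.0 < p <= 1.0):
            raise ValueError(f"row {i}: purity {p} outside (0, 1]")
        out[row.sample_id] = p
    return out


def write_purity(purities: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"sample_id": list(purities), "purity": list(purities.values())}
    ).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Sequence[LesionProfile], path) -> None:
    """Long-format TSV ``patient_id  lesion`` (lesion-free patients get a
    single row with an empty lesion field)."""
    rows = []
    for p in profiles:
        if p.lesions:
            rows.extend({"patient_id": p.patient_id, "lesion": l} for l in sorted(p.lesions))
        else:
            rows.append({"patient_id": p.patient_id, "lesion": ""})
    pd.DataFrame(rows, columns=["patient_id", "lesion"]).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[LesionProfile]:
    """Rebuild profiles from the long format.

    Subtype and IKZF1 status are reconstructed from the lesion tokens; the
    long format implies all IKZF1-status loci were assessed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    profiles = []
    for pid, grp in df.groupby("patient_id", sort=True):
        lesions = frozenset(l for l in grp["lesion"] if l)
        subtype = next((s for s in SUBTYPE_PRECEDENCE[:-1] if s in lesions), "B-other")
        assessed = frozenset(IKZF1_STATUS_LOCI)
        status = _ikzf1_status_from(lesions, assessed)
        profiles.append(
            LesionProfile(
                patient_id=str(pid), lesions=lesions, assessed_loci=assessed,
                subtype=subtype, ikzf_status=status,
            )
        )
    return profiles


def read_score_table(path) -> ScoreTable:
    with open(path) as fh:
        return ScoreTable.from_dict(json.load(fh))


def write_score_table(table: ScoreTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_caller_config(path) -> CallerConfig:
    with open(path) as fh:
        return CallerConfig.from_dict(json.load(fh))


def read_derive_config(path) -> DeriveConfig:
    with open(path) as fh:
        return DeriveConfig.from_dict(json.load(fh))


def read_ikaros_matrix(path) -> IkarosMatrix:
    with open(path) as fh:
        return IkarosMatrix.from_dict(json.load(fh))


def write_ikaros_matrix(matrix: IkarosMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(matrix.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = json.load(fh)
    fields = SimulationConfig.__dataclass_fields__
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("purity_range", "purity_beta", "subclonal_fraction_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def write_calls(calls: pd.DataFrame, path) -> None:
    cols = ["sample_id", "locus", "state", "clonality", "n_probes", "mean_dq", "flags"]
    calls[cols].to_csv(path, sep="\t", index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    command: str,
    inputs: Mapping[str, str | Path],
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Provenance record for one CLI run (input hashes, seed, version)."""
    cfg_hash = None
    if config is not None:
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
    return {
        "command": command,
        "inputs": {name: _sha256(p) for name, p in sorted(inputs.items())},
        "config_hash": cfg_hash,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
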