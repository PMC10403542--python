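"""Probe panel definition for digitalMLPA-style copy-number screening.

A panel mixes three probe roles:

* ``target`` probes interrogating genes recurrently altered in B-ALL
  (several probes per gene, exon-resolved for *IKZF1*),
* ``reference`` digital-karyotyping probes covering every chromosome arm,
  which double as the normalization reference, and
* ``control`` probes used only for per-sample quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProbePanel", "build_default_panel", "CHROMOSOMES", "ACROCENTRIC"]

#: Chromosome labels used throughout; Y is not modelled (baseline 46 = 22
#: autosome pairs plus an XX-equivalent pair of sex chromosomes).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

#: Acrocentric chromosomes carry digital-karyotyping probes on the q arm only.
ACROCENTRIC: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})

_ROLES = ("target", "reference", "control")

_COLUMNS = ["probe_id", "chrom", "position", "arm", "gene", "exon", "role"]


@dataclass
class ProbePanel:
    """Immutable description of every probe's genomic target and role.

    Parameters
    ----------
    table
        DataFrame with columns ``probe_id chrom position arm gene exon role``.
        ``gene`` and ``exon`` are empty strings for reference/control probes;
        ``position`` is 1-based.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["exon"] = t["exon"].fillna("").astype(str)
        t["gene"] = t["gene"].fillna("").astype(str)
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe_ids in panel: {dup}")
        bad_roles = set(t["role"]) - set(_ROLES)
        if bad_roles:
            raise ValueError(f"unknown probe roles: {sorted(bad_roles)}")
        ref = t[t["role"] == "reference"]
        if len(ref) < 8:
            raise ValueError("panel needs at least 8 reference probes")
        if ref[["chrom", "arm"]].drop_duplicates().shape[0] < 2:
            raise ValueError("reference probes must span at least 2 chromosome arms")
        object.__setattr__(self, "table", t)

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    @property
    def reference_probe_ids(self) -> list[str]:
        return self.table.loc[self.table["role"] == "reference", "probe_id"].tolist()

    @property
    def control_probe_ids(self) -> list[str]:
        return self.table.loc[self.table["role"] == "control", "probe_id"].tolist()

    @property
    def target_genes(self) -> list[str]:
        genes = self.table.loc[self.table["role"] == "target", "gene"]
        return sorted(set(genes) - {""})

    def probes_for_gene(self, gene: str) -> pd.DataFrame:
        """Target probes of one gene, ordered by genomic position."""
        sub = self.table[(self.table["role"] == "target") & (self.table["gene"] == gene)]
        if sub.empty:
            raise KeyError(f"gene {gene!r} not in panel")
        return sub.sort_values("position")

    def arm_probes(self) -> pd.DataFrame:
        """Reference (digital-karyotyping) probes, one row per probe."""
        return self.table[self.table["role"] == "reference"]


# Target genes of the default demo panel with probe counts; mirrors the
# recurrently altered loci interrogated by MLPA-based B-ALL screens.
_DEFAULT_GENES: dict[str, tuple[str, int]] = {
    # gene: (chrom, n probes)
    "CDKN2A/B": ("9", 2),
    "PAX5": ("9", 2),
    "MLLT3": ("9", 2),
    "ETV6": ("12", 3),
    "VPREB1": ("22", 2),
    "RUNX1": ("21", 3),
    "BTG1": ("12", 2),
    "RB1": ("13", 2),
    "BTLA/CD200": ("3", 2),
    "CASP8AP2": ("6", 2),
    "TBL1XR1": ("3", 2),
    "TP53": ("17", 2),
    "EBF1": ("5", 2),
    "NR3C1": ("5", 2),
    "ERG": ("21", 2),
    "PAR1": ("X", 2),
}

#: IKZF1 probe labels in genomic order: two upstream probes (~4 kb and ~2 kb
#: upstream of the coding sequence) then one probe per exon 1-8.
IKZF1_PROBE_ORDER: tuple[str, ...] = ("up4kb", "up2kb") + tuple(
    f"ex{i}" for i in range(1, 9)
)


def build_default_panel() -> ProbePanel:
    """Construct the built-in demo panel.

    41 digital-karyotyping reference probes (p and q arm of every
    non-acrocentric autosome and of X, q arm only for acrocentrics), exon
    resolution for *IKZF1* (two upstream probes plus exons 1-8), 2-3 probes
    for each other target gene, and 8 internal control probes.
    """
    rows: list[dict] = []
    pos = 1_000_000
    for chrom in CHROMOSOMES:
        arms = ("q",) if chrom in ACROCENTRIC else ("p", "q")
        for arm in arms:
            rows.append(
                dict(probe_id=f"ref_{chrom}{arm}", chrom=chrom, position=pos,
                     arm=arm, gene="", exon="", role="reference")
            )
            pos += 1_000_000
    for i, label in enumerate(IKZF1_PROBE_ORDER):
        rows.append(
            dict(probe_id=f"IKZF1_{label}", chrom="7", position=50_000_000 + 4_000 * i,
                 arm="p", gene="IKZF1", exon=label, role="target")
        )
    for gene, (chrom, n) in _DEFAULT_GENES.items():
        safe = gene.replace("/", "_")
        for i in range(n):
            rows.append(
                dict(probe_id=f"{safe}_{i + 1}", chrom=chrom,
                     position=20_000_000 + 10_000 * i, arm="q", gene=gene,
                     exon="", role="target")
            )
    for i in range(8):
        rows.append(
            dict(probe_id=f"ctrl_{i + 1}", chrom=str((i % 8) + 1),
                 position=5_000_000 + i, arm="p", gene="", exon="", role="control")
        )
    return ProbePanel(pd.DataFrame(rows, columns=_COLUMNS))
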