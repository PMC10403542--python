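import numpy as np
import pandas as pd
import pytest

import personall as pa


@pytest.fixture(scope="session")
def panel():
    return pa.build_default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with Poisson read counts, shared across tests."""
    cfg = pa.SimulationConfig(n_patients=60, seed=11, dispersion=0)
    records, profiles, truth = pa.generate_cohort(cfg)
    return cfg, records, profiles, truth


@pytest.fixture(scope="session")
def tiny_panel():
    """A minimal hand-built panel: 8 reference probes on two arms, one
    2-probe gene, one control probe."""
    rows = []
    for i in range(4):
        rows.append(dict(probe_id=f"r1p_{i}", chrom="1", position=100 + i,
                         arm="p", gene="", exon="", role="reference"))
        rows.append(dict(probe_id=f"r2q_{i}", chrom="2", position=200 + i,
                         arm="q", gene="", exon="", role="reference"))
    rows.append(dict(probe_id="G_1", chrom="3", position=300, arm="q",
                     gene="G", exon="", role="target"))
    rows.append(dict(probe_id="G_2", chrom="3", position=301, arm="q",
                     gene="G", exon="", role="target"))
    rows.append(dict(probe_id="c_1", chrom="4", position=400, arm="p",
                     gene="", exon="", role="control"))
    return pa.ProbePanel(pd.DataFrame(rows))
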