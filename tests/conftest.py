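import numpy as np
import pandas as pd
import pytest

import clonetrace as ct


@pytest.fixture(scope="session")
def pattern():
    return ct.DEFAULT_BARCODE_PATTERN


@pytest.fixture(scope="session")
def whitelist(pattern):
    return ct.make_whitelist(pattern, n=725, seed=42)


@pytest.fixture(scope="session")
def small_whitelist(pattern):
    return ct.make_whitelist(pattern, n=40, seed=7)


@pytest.fixture()
def toy_ct_table():
    """3 cells x (Hprt + 3 genes); one cell fails housekeeping QC at 21."""
    df = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "KLG"],
            "Hprt": [18.0, 25.0, 19.0],
            "Gata1": [25.0, 24.0, "Fail"],
            "Mpo": [23.0, 999.0, 22.0],
            "Klf1": ["Fail", 30.0, 28.0],
        },
        index=pd.Index(["c1", "c2", "c3"], name="cell"),
    )
    return df.astype(object)


@pytest.fixture(scope="session")
def qc_expression():
    """Normalized expression from a small synthetic two-genotype Ct run."""
    cfg = ct.simulate.null_ct_config(n_cells=60, detection_p=0.6, seed=5)
    sim = ct.simulate_ct_table(cfg)
    table = ct.CtTable(ct=sim.ct, genotype=sim.genotype, panel=sim.panel)
    table, _ = ct.housekeeping_qc(table, cutoff=21.0)
    return ct.normalize_expression(table)
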