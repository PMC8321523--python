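import numpy as np
import pandas as pd
import pytest

from persevo import sim_core
from persevo.barcode_analysis import BarcodeCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_count_table(counts: dict, is_control: dict | None = None) -> BarcodeCountTable:
    """Small BarcodeCountTable from {sample_id: {design_id: count}}.

    Sample ids must look like 'rep<k>_<before|after>'.
    """
    counts_df = pd.DataFrame(counts).fillna(0).astype(np.int64)
    counts_df.index.name = "design_id"
    design_meta = pd.DataFrame(
        {"is_control": [bool((is_control or {}).get(d, False)) for d in counts_df.index]},
        index=counts_df.index,
    )
    meta = []
    for sid in counts_df.columns:
        rep, timepoint = sid.rsplit("_", 1)
        meta.append({"sample_id": sid, "replicate": rep, "timepoint": timepoint,
                     "bottleneck": 0.1, "arm": "selection"})
    sample_meta = pd.DataFrame(meta).set_index("sample_id")
    return BarcodeCountTable(counts=counts_df, design_meta=design_meta, sample_meta=sample_meta)


@pytest.fixture
def two_genotype_pop():
    a = sim_core.GenotypeSpec(id="A", pi=1e-3)
    b = sim_core.GenotypeSpec(id="B", pi=1e-2)
    return sim_core.PopulationState(
        counts={"A": 1000, "B": 500}, genotypes={"A": a, "B": b}
    )
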