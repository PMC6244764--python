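import numpy as np
import pandas as pd
import pytest

from gcqsrr import descriptors as dm
from gcqsrr import splitting
from gcqsrr import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """300-compound synthetic dataset shared across read-only tests."""
    cfg = sd.SyntheticConfig(seed=11, n_compounds=300)
    records, table, series, truth = sd.generate_dataset(cfg)
    return cfg, records, table, series, truth


@pytest.fixture(scope="session")
def study():
    """Full-scale study: 600 compounds, autoscaled descriptors, PCA split.

    Mirrors the complete modelling workflow once so the expensive pieces are
    computed a single time.
    """
    cfg = sd.SyntheticConfig(seed=1, n_compounds=600)
    records, table, series, truth = sd.generate_dataset(cfg)
    scaled, params = dm.autoscale(table)
    pca = splitting.run_pca(scaled.values, n_components=5, scale=False)
    pcb = {
        r.compound_id: r.chlorination_level
        for r in records
        if r.chlorination_level is not None
    }
    assign = splitting.systematic_split(
        [r.compound_id for r in records], pca.scores, seed=7, pcb_levels=pcb
    )
    responses = pd.DataFrame(
        {
            "t1R_s": [r.t1r for r in records],
            "t2R_s": [r.t2r for r in records],
            "LRI": [r.lri for r in records],
            "PEG2I": [r.peg2i for r in records],
            "group": [r.group for r in records],
        },
        index=pd.Index([r.compound_id for r in records], name="compound_id"),
    )
    return {
        "cfg": cfg,
        "records": records,
        "table": table,
        "series": series,
        "truth": truth,
        "scaled": scaled,
        "params": params,
        "pca": pca,
        "assign": assign,
        "responses": responses,
    }
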