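import numpy as np
import pandas as pd
import pytest

import fragilexpress as fx


@pytest.fixture(scope="session")
def annotation():
    return fx.default_annotation()


@pytest.fixture()
def small_panel():
    """3 genes x 4 samples (3 tumours, 1 pair of normals would be needed
    for z-scoring; this panel is for IO/validation tests only)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 1.0, 1.5], [10.0, 20.0, 30.0, 40.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "tumour_type": ["COAD"] * 4,
            "is_tumour": [True, True, True, False],
            "purity": [0.8, 0.6, np.nan, np.nan],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return fx.ExpressionPanel(
        values=values, metadata=meta,
        protein_coding=pd.Series([True, True, False], index=values.index),
    )


@pytest.fixture()
def zscore_ready_panel():
    """Panel with enough normals for z-scoring; values chosen by hand."""
    rng = np.random.default_rng(7)
    genes = ["g1", "g2", "g3"]
    tumours = [f"T{i}" for i in range(6)]
    normals = [f"N{i}" for i in range(4)]
    values = pd.DataFrame(
        rng.uniform(1.0, 50.0, size=(3, 10)), index=genes,
        columns=tumours + normals,
    )
    meta = pd.DataFrame(
        {
            "tumour_type": ["COAD"] * 10,
            "is_tumour": [True] * 6 + [False] * 4,
            "purity": list(rng.uniform(0.4, 1.0, 6)) + [np.nan] * 4,
        },
        index=tumours + normals,
    )
    return fx.ExpressionPanel(
        values=values, metadata=meta,
        protein_coding=pd.Series(True, index=values.index),
    )
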