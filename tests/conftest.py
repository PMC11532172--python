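import numpy as np
import pandas as pd
import pytest

from nrbgrn.expression import ExpressionMatrix
from nrbgrn.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study1():
    """Default synthetic study, seed 1, shared across test modules."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tpm1(study1):
    from nrbgrn.quantify import tpm_normalize

    return tpm_normalize(study1.counts)


@pytest.fixture(scope="session")
def de_sets1(study1, tpm1):
    """(floored TPM, nrb set, stage set, intersection) for the seed-1 study."""
    from nrbgrn.de import intersect_deg_sets, nrb_specific_genes, stagewise_degs
    from nrbgrn.quantify import expression_floor

    floored = tpm1.subset_genes(expression_floor(tpm1, 5.0))
    nrb = nrb_specific_genes(floored)
    stage = stagewise_degs(floored)
    return floored, nrb, stage, intersect_deg_sets(nrb, stage)


def toy_matrix(values, unit="TPM", stages=None, tissue=None, lengths=None):
    """Small ExpressionMatrix builder for hand-crafted examples.

    ``values``: dict gene → list of per-sample values.
    """
    df = pd.DataFrame(values).T
    n = df.shape[1]
    df.columns = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": df.columns,
        "stage": pd.array(stages if stages is not None else [1] * n, dtype="Int64"),
        "tissue_class": tissue if tissue is not None else ["NRB"] * n,
        "replicate": list(range(1, n + 1)),
    })
    lser = pd.Series(lengths) if lengths is not None else None
    return ExpressionMatrix(df.astype(float), unit, meta, lser)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
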