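import logging

import numpy as np
import pandas as pd
import pytest

import bfcorr as b
from bfcorr.io_preprocess import ExpressionMatrix

logging.getLogger("bfcorr").setLevel(logging.ERROR)


def make_matrix(values, state="counts", genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes if genes is not None else [f"g{i}" for i in range(values.shape[0])]
    samples = samples if samples is not None else [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), state)


@pytest.fixture(scope="session")
def small_bundle() -> b.FixtureBundle:
    """A compact study-style simulation shared by read-only tests."""
    cfg = b.study_config(n_genes=600, n_tissues=5, samples_per_tissue=4, seed=11)
    return b.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_logged(small_bundle):
    """(biofluid, tissue) log2(TPM+1) matrices for the small bundle."""
    ann = small_bundle.annotation
    lf = b.log_transform(b.tpm_normalize(small_bundle.biofluid_matrix, ann))
    lt = b.log_transform(b.tpm_normalize(small_bundle.tissue_matrix, ann))
    return lf, lt
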