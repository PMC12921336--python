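import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from morgan5c import (
    CohortConfig,
    ExpressionMatrix,
    GeneMethylationMatrix,
    SampleSheet,
    SiteTable,
    simulate_cohort,
    simulate_site_fixture,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    return simulate_cohort(CohortConfig(seed=11, n_genes=60, n_driven=5))


@pytest.fixture(scope="session")
def site_fixture():
    """Default site-level fixture: genome, annotation, tables, truth, metadata."""
    return simulate_site_fixture(seed=0)


@pytest.fixture()
def toy_metadata():
    return SampleSheet(
        {"t1": "cancer", "t2": "cancer", "t3": "cancer", "n1": "normal", "n2": "normal"}
    )


def make_site_table(sample_id, rows):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "coverage", "methylated", "meth_rate", "gene"],
    )
    return SiteTable(sample_id, df)


def make_expression(values, genes=None, samples=None, scale="raw_counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def make_methylation(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return GeneMethylationMatrix(pd.DataFrame(values, index=genes, columns=samples))
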