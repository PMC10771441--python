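import numpy as np
import pandas as pd
import pytest

from hltme.containers import ClinicalTable, ExpressionMatrix, SignatureMatrix
from hltme.io import normalize_counts
from hltme.synthetic import SimulationConfig, discovery_config, generate_cohort


@pytest.fixture(scope="session")
def discovery_cohort():
    """Discovery-preset synthetic cohort (25 samples, 800 genes), seed 0."""
    return generate_cohort(discovery_config(seed=0))


@pytest.fixture(scope="session")
def discovery_normalized(discovery_cohort):
    return normalize_counts(discovery_cohort.expression,
                            list(discovery_cohort.housekeeping_genes))


@pytest.fixture
def tiny_config():
    """A fast two-cell-type configuration for unit-level synthetic tests."""
    return SimulationConfig(
        n_favorable=4, n_unfavorable=4, n_celltypes=2, n_markers_per_type=2,
        n_housekeeping=3, total_genes=20,
        celltype_names=("Type A", "Type B"), adverse_types=("Type B",),
        adverse_pathways=(), seed=7,
    )


@pytest.fixture
def toy_expression():
    values = pd.DataFrame(
        [[10.0, 20.0], [5.0, 3.0], [1.0, 9.0]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(values=values, scale="raw")


@pytest.fixture
def toy_clinical():
    return ClinicalTable(table=pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4", "S5", "S6"],
        "outcome": ["F", "F", "F", "U", "U", "U"],
        "pfs_months": [60.0, 48.0, 30.0, 10.0, 5.0, 20.0],
        "event": [0, 1, 0, 1, 1, 1],
    }))
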