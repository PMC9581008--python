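import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import peparray as pa
from peparray.preprocess import IntensityMatrix, Provenance

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, cohorts, peptide_ids=None, sample_ids=None, mode="foreground"):
    """Small IntensityMatrix straight from an array, for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    peptide_ids = peptide_ids or [f"P{i + 1}" for i in range(n)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(m)]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=peptide_ids, columns=sample_ids),
        cohorts=dict(zip(sample_ids, cohorts)),
        sequences=pd.Series(["ACDEFGHIKLMNPQR"] * n, index=peptide_ids),
        provenance=Provenance(intensity_mode=mode, aggregated=True),
    )


@pytest.fixture(scope="session")
def small_experiment():
    """101 tiled peptides, triplicate, 4+4 samples, 5% spiked at 4 sigma."""
    spec = pa.SimSpec(seed=1, protein_length=415, n_control=4, n_treatment=4)
    samples, truth = pa.simulate_samples(spec)
    return spec, samples, truth


@pytest.fixture(scope="session")
def null_experiment():
    """Reference null conditions: 2,000 peptides, 10+10 samples, zero effect."""
    spec = pa.SimSpec(seed=11, differential_fraction=0.0)
    samples, truth = pa.simulate_samples(spec)
    matrix = pa.assemble_matrix(samples)
    return spec, samples, truth, matrix


@pytest.fixture(scope="session")
def null_table(null_experiment):
    _, _, _, matrix = null_experiment
    return pa.build_synoptic_table(pa.quantile_normalize(matrix))


@pytest.fixture(scope="session")
def power_experiment():
    """Reference spiked conditions: 5% of 2,000 peptides at 4 sigma, 10+10."""
    spec = pa.SimSpec(seed=7)
    samples, truth = pa.simulate_samples(spec)
    table = pa.build_synoptic_table(pa.quantile_normalize(pa.assemble_matrix(samples)))
    return spec, truth, table


@pytest.fixture(scope="session")
def small_table(small_experiment):
    _, samples, _ = small_experiment
    return pa.build_synoptic_table(pa.quantile_normalize(pa.assemble_matrix(samples)))
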