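import numpy as np
import pandas as pd
import pytest

from cerna_ti.io_formats import ExpressionMatrix
from cerna_ti.synthetic_data import SimulationConfig, generate_dataset, toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The hard-coded 12-gene, 2-patient x 5-time-point fixture."""
    return toy_fixture()


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (seed 11), shared across tests."""
    return generate_dataset(SimulationConfig(seed=11))


def make_expression(values: np.ndarray, n_times: int = 5,
                    biotype: str = "mRNA") -> ExpressionMatrix:
    """Wrap a raw non-negative (genes x samples) array as an ExpressionMatrix.

    Samples are laid out as ``ceil(n_samples / n_times)`` patients times
    ``n_times`` time points 0, 2, 12, 24, 72, ... (extended if needed).
    """
    n_genes, n_samples = values.shape
    base_times = [0, 2, 12, 24, 72]
    while len(base_times) < n_times:
        base_times.append(base_times[-1] * 2)
    times = base_times[:n_times]
    samples, patients, hours = [], [], []
    p = 0
    while len(samples) < n_samples:
        p += 1
        for t in times:
            if len(samples) == n_samples:
                break
            samples.append(f"P{p}_t{t:g}")
            patients.append(f"P{p}")
            hours.append(float(t))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        biotype=pd.Series([biotype] * n_genes, index=genes),
        sample_meta=pd.DataFrame({"patient": patients, "time_hours": hours},
                                 index=pd.Index(samples, name="sample")),
    )
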