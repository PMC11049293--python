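import numpy as np
import pandas as pd
import pytest

from synaptomics import Design, QuantMatrix, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-protein simulated experiment shared across read-only tests."""
    cfg = SimulationConfig(n_proteins=300, seed=42, missing_rate=0.02)
    spectra, matrix, truth, design = simulate_experiment(cfg)
    return {"config": cfg, "spectra": spectra, "matrix": matrix,
            "truth": truth, "design": design}


@pytest.fixture()
def balanced_design():
    return Design.balanced(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, design, prefix="P"):
    values = np.asarray(values, dtype=float)
    return QuantMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:03d}" for i in range(values.shape[0])],
            columns=design.samples,
        )
    )
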