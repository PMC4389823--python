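"""Shared fixtures: small SEMs, simulated matrices, designs."""

import numpy as np
import pandas as pd
import pytest

from apoptonet.dags import make_dag
from apoptonet.datasets import SampleDesign, SemParams, simulate_sem


@pytest.fixture
def chain_sem():
    """X -> Y -> Z with beta 2 / -1.5, unit intercepts zero, sigma2 1."""
    dag = make_dag("XYZ", [("X", "Y"), ("Y", "Z")])
    return SemParams(
        dag=dag,
        beta={("X", "Y"): 2.0, ("Y", "Z"): -1.5},
        alpha={g: 0.0 for g in "XYZ"},
        sigma2={g: 1.0 for g in "XYZ"},
    )


@pytest.fixture
def chain_data(chain_sem):
    """500 samples from the chain SEM (strong, easily recoverable signal)."""
    return simulate_sem(chain_sem, 500, seed=11)


@pytest.fixture
def independent_data():
    """Two independent noise genes, 300 samples."""
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        rng.standard_normal((2, 300)), index=["A", "B"],
        columns=[f"s{i}" for i in range(300)],
    )


@pytest.fixture
def small_design():
    ids = tuple(f"s{i}" for i in range(10))
    return SampleDesign(ids, ("control",) * 4 + ("perturbed",) * 6)
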