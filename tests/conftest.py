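import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cfnet.simulate import SimConfig, simulate_study
from cfnet.types import ElutionMatrix


@pytest.fixture(scope="session")
def small_study():
    """A small default-noise study shared by read-only tests."""
    return simulate_study(SimConfig(n_proteins=60, n_complexes=8, seed=7))


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(3)
    values = rng.uniform(0, 100, size=(5, 12))
    values[0, 3] = np.nan
    values[2, :6] = np.nan
    return ElutionMatrix(
        experiment_id="e1",
        species="test",
        proteins=["A", "B", "C", "D", "E"],
        intensities=values,
    )
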