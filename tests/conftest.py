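import numpy as np
import pandas as pd
import pytest

from facstress import StressFactorialModel, simulate
from facstress.design import DesignSpec, make_design


@pytest.fixture(scope="session")
def small_dataset():
    """Standard small simulation: 400 genes, 64 samples, batch present."""
    return simulate.simulate_dataset(n_genes=400, seed=11)


@pytest.fixture(scope="session")
def fitted(small_dataset):
    design, truth, tx, sf = small_dataset
    model = StressFactorialModel.from_transcripts(tx, design)
    return model.fit(seed=11)


@pytest.fixture(scope="session")
def design64():
    return make_design(DesignSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
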