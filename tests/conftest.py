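import numpy as np
import pytest

from rsca.data_model import MultiBlockData, preprocess
from rsca.simulation import SimulationDesign, generate_dataset, study_cells


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_data(rng):
    """Small preprocessed 2-block dataset (10 rows, 6 + 4 columns)."""
    return preprocess(
        MultiBlockData(
            [rng.standard_normal((10, 6)), rng.standard_normal((10, 4))],
            block_names=["left", "right"],
        )
    )


@pytest.fixture(scope="session")
def planted():
    """One generated dataset of the smallest design cell plus its truth."""
    design = study_cells(1)[0]  # 20x40 + 20x10, sparsity .3, noise .005
    return generate_dataset(design, 2024)


@pytest.fixture(scope="session")
def tiny_design():
    """A small custom cell for fast end-to-end checks."""
    return SimulationDesign(
        block_dims=((12, 8), (12, 5)),
        structure_mask=np.array([[True, False, True], [True, True, False]]),
        sparsity=0.3,
        noise_fraction=0.005,
    )
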