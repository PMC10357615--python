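import numpy as np
import pandas as pd
import pytest

from amyloprot.design import StudyDesign
from amyloprot.io_tables import IntensityMatrix
from amyloprot.pipeline import RunConfig, run_all


@pytest.fixture(scope="session")
def smoke_results():
    """One end-to-end run of the small preset, shared across tests."""
    return run_all(RunConfig(seed=1, preset="5xfad-smoke"))


@pytest.fixture
def one_tissue_design():
    return StudyDesign(tissues=("cortex",))


def make_matrix(values: np.ndarray, meta: pd.DataFrame, prefix: str = "P") -> IntensityMatrix:
    ids = [f"{prefix}{i + 1:04d}" for i in range(values.shape[0])]
    return IntensityMatrix(
        pd.DataFrame(values, index=ids, columns=meta["sample"]), meta.reset_index(drop=True)
    )


@pytest.fixture
def toy_matrix_factory():
    return make_matrix
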