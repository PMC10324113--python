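import numpy as np
import pytest

from popkit import (
    PKDataset,
    PopulationModel,
    SAEMConfig,
    StructuralParams,
    default_paper_design,
    default_truth,
    simulate_study,
)


@pytest.fixture(scope="session")
def table_params() -> StructuralParams:
    """Typical-value structural parameters used throughout the suite."""
    return StructuralParams(cl=0.32, v=1.88, ka=1.20)


@pytest.fixture(scope="session")
def default_dataset() -> tuple[PKDataset, "object"]:
    ds, truth = simulate_study(default_paper_design(), default_truth(), seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def quick_cfg() -> SAEMConfig:
    """Reduced SAEM configuration for fast tests."""
    return SAEMConfig(k1=150, k2=75, seed=0, compute_loglik=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_single_group_model(omega_diag=(0.09, 0.09, 0.09), a=2.0) -> PopulationModel:
    return PopulationModel(
        theta=(0.32, 1.88, 1.20),
        beta={"G1": 0.0},
        omega=np.diag(omega_diag),
        error_model="additive",
        error_params=(a, 0.0),
    )
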