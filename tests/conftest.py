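import numpy as np
import pytest

from lsdsm.canonical import ModelParameters, build_canonical_structure
from lsdsm.gridding import grid_patient
from lsdsm.simulate import SimConfig, default_true_model, simulate_cohort


@pytest.fixture
def ar1_params():
    """A 1-state (AR(1), single biomarker) model with a real hazard link."""
    s = build_canonical_structure(m_y=1, M=1, m_omega=1)
    return ModelParameters(
        structure=s,
        A_bar=[[0.9]],
        W_breve=[[0.3]],
        V=[[0.2]],
        x1_bar=[1.0],
        W1_bar=[[0.5]],
        gamma=[-1.5],
        alpha=[-0.8],
    )


@pytest.fixture
def ar2_params():
    """The default AR(2) generating model."""
    return default_true_model()


@pytest.fixture
def toy_patient():
    return grid_patient(
        [0, 1, 2, 3],
        [[1.2], [0.8], [0.5], [0.6]],
        omega=[1.0],
        T=4.0,
        delta=0,
        dt=1.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort for estimation smoke tests."""
    return simulate_cohort(config=SimConfig(n=80, seed=123))
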