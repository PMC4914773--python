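import numpy as np
import pytest

from mekerk.models import ParamVector, build_distributive_model, build_processive_model
from mekerk.synthetic import (
    AcquisitionDesign,
    default_times,
    generate_qic_dataset,
    reference_hyperparameters,
)


@pytest.fixture(scope="session")
def dist_model():
    return build_distributive_model()


@pytest.fixture(scope="session")
def proc_model():
    return build_processive_model()


@pytest.fixture(scope="session")
def times26():
    return default_times()


@pytest.fixture(scope="session")
def fixture_ex():
    return reference_hyperparameters("extrinsic")


@pytest.fixture(scope="session")
def theta_ref(fixture_ex):
    """Population-mean parameter vector of the reference fixture."""
    return fixture_ex.theta


@pytest.fixture(scope="session")
def small_snapshot(fixture_ex):
    """Tiny extrinsic snapshot (30 cells x 26 times) for likelihood tests."""
    design = AcquisitionDesign(times=default_times(), n_per_time=30, seed=42)
    return generate_qic_dataset(fixture_ex, design)


@pytest.fixture
def decoupled_theta(dist_model):
    """All association rates zero: the M subsystem is a linear birth-death
    process decoupled from the ERK cycle."""
    vals = {n: 0.0 for n in dist_model.param_names}
    vals.update(k1=1.0, k2=0.1, k10=1.0, T_pulse=5.0,
                E_tot=100.0, P_tot=10.0, M0=0.0, Epp0=0.0)
    return ParamVector(dist_model.param_names, vals)
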