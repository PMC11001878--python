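import numpy as np
import pytest

from catchslip.elasticity import EnergyProfile, ThermalContext
from catchslip.kinetics import (
    EXPERIMENT_SPEEDS,
    PullProtocol,
    bond_model_for_geometry,
    simulate_constant_speed,
)


@pytest.fixture(scope="session")
def ctx():
    return ThermalContext()


@pytest.fixture(scope="session")
def nnb_profile():
    """Single-pathway slip landscape (log10 k0 = -4.2, dx = 0.65 nm)."""
    return EnergyProfile.from_log10_k0(-4.2, 0.65)


@pytest.fixture(scope="session")
def catch_model():
    return bond_model_for_geometry("NN-C")


@pytest.fixture(scope="session")
def native_model():
    return bond_model_for_geometry("native")


@pytest.fixture(scope="session")
def nnc_records_by_speed(catch_model, ctx):
    """One NN-C constant-speed batch per experimental speed (n=1000 each)."""
    return {
        V: simulate_constant_speed(catch_model, PullProtocol(V=V), 1000,
                                   seed=7000 + i, ctx=ctx)
        for i, V in enumerate(EXPERIMENT_SPEEDS)
    }


@pytest.fixture(scope="session")
def native_records_by_speed(native_model, ctx):
    return {
        V: simulate_constant_speed(native_model, PullProtocol(V=V), 1000,
                                   seed=8000 + i, ctx=ctx)
        for i, V in enumerate(EXPERIMENT_SPEEDS)
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
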