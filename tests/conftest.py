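"""Shared fixtures: one synthetic tide, site models, and a clean
(noiseless) calibration core, built once per session."""

import pytest

from tidalmarsh import (
    DecompParams,
    MixingModel,
    RootParams,
    SedimentParams,
    default_harmonics,
    synthesize_tide,
)
from tidalmarsh import engine, synth


@pytest.fixture(scope="session")
def mix():
    return MixingModel()


@pytest.fixture(scope="session")
def decomp():
    return DecompParams()


@pytest.fixture(scope="session")
def root():
    return RootParams()


@pytest.fixture(scope="session")
def tide():
    return synthesize_tide(default_harmonics(), 1.92)


@pytest.fixture(scope="session")
def sed():
    return SedimentParams(C0=69.0)


@pytest.fixture(scope="session")
def petaluma_model():
    return synth.make_model("petaluma")


@pytest.fixture(scope="session")
def browns_model():
    return synth.make_model("browns_island")


@pytest.fixture(scope="session")
def spun_browns(browns_model):
    """Equilibrated column/community at the oligohaline site's mean
    elevation (0.42 m MSL)."""
    col, state, rate = engine.spin_up(browns_model, 42.0)
    return col, state, rate


@pytest.fixture(scope="session")
def clean_core():
    """Noiseless synthetic core at C_true = 50 mg/L with its model."""
    spec = synth.SyntheticSiteSpec(C_true_mg_l=50.0, noise_rho=0.0, noise_o=0.0, seed=3)
    model = synth.make_model(spec)
    core, manifest = synth.make_synthetic_core(spec, model=model)
    return spec, model, core, manifest
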