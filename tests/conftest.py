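"""Shared fixtures: the calibrated default model, noiseless synthetic trials,
and constructed hinge fixtures with known mechanics."""

from dataclasses import replace

import pytest

from stsim import pipeline as P
from stsim import synth


@pytest.fixture(scope="session")
def cfg_clean():
    return replace(synth.SynthConfig(), marker_noise_sd=0.0, force_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_model(cfg_clean):
    return synth.default_model(cfg_clean)


@pytest.fixture(scope="session")
def clean_trial(cfg_clean, default_model):
    return synth.synth_trial(cfg_clean, model=default_model)


@pytest.fixture(scope="session")
def nominal_run(cfg_clean, default_model, clean_trial):
    """Full noiseless pipeline output, shared across tests."""
    return P.run_sts_analysis(clean_trial.markers, clean_trial.wrench_truth,
                              default_model)


# constructed fixture with exactly known torque capacities
make_hinge_model = synth.hinge_fixture_model


@pytest.fixture()
def hinge_posture():
    return (-56.7, -79.2, -84.4)
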