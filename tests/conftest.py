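"""Shared fixtures: small synthetic studies generated at test time."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import fpvs
from fpvs.config import SimulationConfig


@pytest.fixture(scope="session")
def tiny_study():
    """A 2-participant full-waveform study with default noise."""
    cfg = SimulationConfig(n_participants=2)
    return fpvs.simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_study):
    """Preprocessed epochs of the 2-participant study."""
    from fpvs.preprocess import preprocess_study

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs, log = preprocess_study(tiny_study)
    return epochs


@pytest.fixture()
def clean_profile():
    """A noiseless participant with unit-ish response amplitudes."""
    from fpvs.simulate import draw_profile

    cfg = SimulationConfig(
        noise_scale=0.0, alpha_burst_amp=0.0, blink_rate_mean=0.0, blink_rate_sd=0.0
    )
    prof = draw_profile(1, cfg, np.random.default_rng(0))
    prof.noise_scale = 0.0
    prof.blink_rate = 0.0
    return prof


@pytest.fixture()
def quiet_config():
    """Simulation config with all nuisance components switched off."""
    return SimulationConfig(
        noise_scale=0.0, alpha_burst_amp=0.0, blink_rate_mean=0.0, blink_rate_sd=0.0
    )
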