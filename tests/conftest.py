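"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import phagopulse as pp


@pytest.fixture(scope="session")
def noisefree_pulsing_cohort():
    """Noise-free cohort, every phagosome pulsing with well-separated schedules."""
    cfg = pp.SimConfig(
        n_neutrophils=6, phagosomes_min=1, phagosomes_max=1, p_pulse=1.0,
        n_frames=200, latency_mean_min=20.0, latency_sd_min=5.0,
        interpulse_min_gap_min=4.0, interpulse_mean_min=10.0, seed=42,
    )
    movies, log = pp.simulate_cohort(cfg)
    return cfg, movies, log


@pytest.fixture(scope="session")
def snr8_cohort():
    """Reference-noise cohort (SNR 8) with the cohort-default pulse schedule."""
    cfg = pp.SimConfig.with_snr(
        8.0, n_neutrophils=6, phagosomes_min=2, phagosomes_max=4, p_pulse=0.5,
        n_frames=120, seed=7,
    )
    movies, log = pp.simulate_cohort(cfg)
    return cfg, movies, log


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
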