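"""Shared fixtures: small synthetic profiles and cached cohort artifacts."""

from dataclasses import replace

import numpy as np
import pytest

from pdspeech.synthvoice import HC_PROFILE, PD_PROFILE, SynthProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hc() -> SynthProfile:
    """HC-like profile shortened for fast unit tests."""
    return replace(HC_PROFILE, n_utterings=4, uttering_dur=(0.5, 0.1), pause_dur=(0.3, 0.08))


@pytest.fixture
def small_pd() -> SynthProfile:
    return replace(PD_PROFILE, n_utterings=6, uttering_dur=(0.4, 0.1), pause_dur=(0.4, 0.1))


@pytest.fixture
def clean_hc(small_hc) -> SynthProfile:
    """Noise-free short profile (known segmentation exactly recoverable)."""
    return replace(small_hc, noise_snr_db=np.inf)


@pytest.fixture
def steady_voice() -> SynthProfile:
    """Deterministic-pitch profile: no jitter, no drift, no AM."""
    return replace(HC_PROFILE, f0_sd=0.0, jitter=0.0, loudness_sd=0.0)
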