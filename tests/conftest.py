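import numpy as np
import pytest

from eptools.synthetic import (
    NoiseModel,
    SignalComponent,
    default_components,
    make_itinerary,
    synth_trace,
)

QUIET = NoiseModel(baseline=100.0, white_sigma=0.0, drift_amplitude=0.0)


@pytest.fixture
def lymnaeid_itinerary():
    """Preset lymnaeid itinerary without jitter (rotation 40 h ... hatch 240 h)."""
    return make_itinerary("lymnaeid", jitter_sigma=0.0)


@pytest.fixture
def heart_component():
    return SignalComponent("heart", 2.0, 0.0, 3.0, "heart", "sinusoid")


@pytest.fixture
def quiet_noise():
    return QUIET


def sinusoid_trace(amplitude=3.0, freq=2.0, fps=30.0, duration=30.0, clip_time=200.0, seed=0):
    """Noise-free single-sinusoid trace, active (clip after heart onset)."""
    itin = make_itinerary("lymnaeid", jitter_sigma=0.0)
    comp = [SignalComponent("heart", freq, 0.0, amplitude, "heart", "sinusoid")]
    return synth_trace(itin, comp, QUIET, clip_time=clip_time, fps=fps, duration=duration, rng_seed=seed)


def full_signal_trace(clip_time=220.0, fps=30.0, seed=0, noise=None):
    """Trace with all four default components active."""
    itin = make_itinerary("lymnaeid", jitter_sigma=0.0)
    return synth_trace(
        itin,
        default_components(),
        noise or NoiseModel(),
        clip_time=clip_time,
        fps=fps,
        duration=30.0,
        rng_seed=seed,
    )
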