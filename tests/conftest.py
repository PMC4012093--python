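import numpy as np
import pytest

from eitflow import LungModelConfig, VentilatorSettings, analyze_record, simulate_record


@pytest.fixture(scope="session")
def default_vent():
    return VentilatorSettings()


@pytest.fixture(scope="session")
def clean_model():
    """Noise-free, cardiac-free model: every disturbance off."""
    return LungModelConfig(cardiac_rel=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(default_vent, clean_model):
    """One noise-free 60 s default record: (frames, spiro, truth)."""
    return simulate_record(default_vent, clean_model, duration=60.0, seed=1)


@pytest.fixture(scope="session")
def clean_analysis(clean_record):
    frames, _, _ = clean_record
    return analyze_record(frames)


def metric_per_breath(metrics, roi, name):
    return np.asarray([m.value(name) for m in metrics if m.roi == roi])
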