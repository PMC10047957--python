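import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import itwgait as g

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def clean_config() -> g.SyntheticSubjectConfig:
    """Noise-free subject with the default toe-walking / heel-toe waveforms."""
    return g.SyntheticSubjectConfig(noise_sd_mm=0.0)


@pytest.fixture
def clean_trial(clean_config):
    """Noise-free barefoot trial with ground truth (3 cycles)."""
    return g.synthesize_trial(clean_config, g.Condition.BF, n_cycles=3)


@pytest.fixture
def clean_offsets(clean_config):
    return g.calibrate_subject(g.synthesize_static(clean_config))


def constant_cycle(value: float, stance_end: float = 60.0) -> g.NormalizedCycle:
    return g.NormalizedCycle(np.full(101, float(value)), stance_end_pct=stance_end)


@pytest.fixture
def make_cycle():
    """Build a NormalizedCycle from an arbitrary 101-sample array."""

    def _make(samples, stance_end=60.0):
        return g.NormalizedCycle(np.asarray(samples, float), stance_end_pct=stance_end)

    return _make
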