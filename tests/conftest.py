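import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fogkit import io_preprocess as iop
from fogkit import synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_window(freq_hz: float, fs: float = 40.0, amp: float = 1.0,
                n: int = 128) -> np.ndarray:
    """A (128, 3) window with the same sinusoid on all three axes."""
    t = np.arange(n) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return np.tile(x[:, None], (1, 3))


@pytest.fixture(scope="session")
def small_cohort():
    """5 subjects x 2.5 min, one recording each — reused across tests."""
    spec = synthetic.CohortSpec(n_subjects=5, recording_minutes=2.5,
                                n_recordings=1, seed=42)
    return synthetic.simulate_cohort(spec)


@pytest.fixture(scope="session")
def windowsets_75(small_cohort):
    """Preprocessed 75%-overlap window sets for the small cohort."""
    return iop.windowsets_from_recordings(small_cohort, overlap=0.75)
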