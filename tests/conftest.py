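import numpy as np
import pytest

from nirsbreath import CohortConfig, RunConfig, noiseless, run_pipeline


@pytest.fixture()
def default_cfg():
    """Default noisy cohort configuration (the study conditions)."""
    return CohortConfig(seed=0)


@pytest.fixture()
def clean_cfg():
    """Default cohort with cardiac, drift, noise and jitter switched off."""
    return noiseless(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def full_run():
    """One full-experiment run on the default 21-participant cohort with the
    complete 100-repeat evaluation; shared across tests (read-only)."""
    return run_pipeline(RunConfig(seed=0, repeats=100))


def sinusoid(period_s: float, duration_s: float, fs: float = 10.0,
             amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    return amplitude * np.sin(2 * np.pi * t / period_s + phase)
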