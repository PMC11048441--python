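import numpy as np
import pytest

from votkit.pipeline import extract_cohort
from votkit.preprocessing import preprocess_recording
from votkit.synthetic_vot import ProtocolTiming, default_truth, simulate_cohort, simulate_trace
from votkit.vot_features import extract_features


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free, cardiac-free climber-mean recording with its truth."""
    rec, truth = simulate_trace(default_truth("climber"))
    return rec, truth


@pytest.fixture(scope="session")
def clean_features(clean_trace):
    rec, truth = clean_trace
    return extract_features(preprocess_recording(rec)), truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """One realistic-noise cohort (seed 0) with its ground-truth table and
    the extracted feature table; shared across tests for speed."""
    recs, truth = simulate_cohort(seed=0)
    features = extract_cohort(recs)
    return recs, truth, features


@pytest.fixture(scope="session")
def short_protocol():
    """Compressed cuff timing for I/O and pipeline shape tests."""
    return ProtocolTiming(ba_s=80.0, oc_s=60.0, hy_s=180.0)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
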