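import numpy as np
import pytest

from nblandscape.pipeline import run_landscape_pipeline
from nblandscape.simulate import plant_landscape, simulate_peak_landscape


@pytest.fixture(scope="session")
def clean_bundle():
    """40 planted peaks (10 per label), zero noise, zero jitter."""
    truth = plant_landscape(
        n_peaks=40,
        label_fractions={"C": 0.25, "E": 0.25, "D": 0.25, "O": 0.25},
        seed=1,
    )
    truth.noise_rate = 0.0
    return simulate_peak_landscape(truth, jitter=0)


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return run_landscape_pipeline(clean_bundle)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default study conditions at small scale (200 peaks, default noise)."""
    truth = plant_landscape(n_peaks=200, seed=2)
    return simulate_peak_landscape(truth)


def matched_truth(bundle, reference_peak):
    """The unique planted peak overlapping a reference peak."""
    hits = [
        p for p in bundle.truth.planted_peaks
        if p.interval.overlaps(reference_peak.interval)
    ]
    assert len(hits) == 1
    return hits[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
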