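import numpy as np
import pytest

from tetracall import MISSING, MeanModelParams, SimulationConfig, simulate_marker


def call_accuracy(result, true_dosages):
    """Fraction of assigned calls matching the simulated truth.

    True dosages are indexed by the simulator's sample order (ids
    ``S0000``..); samples excluded by the intensity pre-filter are aligned
    away by parsing the retained sample ids.
    """
    assert result.calls is not None
    idx = np.array([int(s[1:]) for s in result.sample_ids])
    truth = np.asarray(true_dosages)[idx]
    assigned = result.calls != MISSING
    if not assigned.any():
        return 0.0
    return float((result.calls[assigned] == truth[assigned]).mean())


@pytest.fixture
def clean_marker():
    """A well-behaved five-peak marker: symmetric channels, HWE p=0.5."""
    cfg = SimulationConfig(
        marker_id="clean",
        model_id=2,
        params=MeanModelParams(2, 0.02, 0.02, 1.0),
        p=0.4,
        sigma=0.04,
        n_samples=224,
        seed=11,
    )
    return simulate_marker(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
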