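import numpy as np
import pytest

from microact import (
    StateSequenceSpec,
    generate_templates,
    get_montage,
    simulate_state_sequence,
    synthesize_eeg,
)


@pytest.fixture(scope="session")
def montage19():
    return get_montage()


@pytest.fixture(scope="session")
def templates4():
    return generate_templates(19, 4, seed=1)


@pytest.fixture(scope="session")
def short_synthetic(templates4):
    """10-s snr=4 recording with truth labels (fast shared fixture)."""
    spec = StateSequenceSpec(k=4, total_duration_s=10.0, seed=1)
    labels = simulate_state_sequence(spec)
    eeg = synthesize_eeg(templates4, labels, 500.0, snr=4.0, seed=1)
    return eeg, spec


def orthogonal_templates(n_channels: int, k: int, seed: int = 0) -> np.ndarray:
    """Exactly orthogonal zero-mean unit-norm maps (test helper)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_channels, k + 1))
    X[:, 0] = 1.0  # force the constant vector into the basis, then drop it
    Q, _ = np.linalg.qr(X)
    return Q[:, 1 : k + 1].T
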