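import numpy as np
import pytest

import eegflow as ef


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale two-class dataset under the frozen study conditions."""
    return ef.make_study_dataset(n_subjects=6, duration_s=60.0, seed=11)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    tensors = [ef.connectivity_for_recording(r, ef.ConnectivityConfig(order=6))
               for r in small_dataset.recordings]
    return ef.feature_table(tensors)


@pytest.fixture(scope="session")
def var1_truth():
    """Stable 2-channel VAR(1) with unidirectional coupling 1 -> 2."""
    a1 = np.array([[0.5, 0.0], [0.4, 0.5]])
    return ef.VARTruth(1, (a1,), np.eye(2), np.zeros(2))


@pytest.fixture
def clean_recording():
    """Artifact-free 14-channel VAR recording with independent sensor noise.

    The sensor noise matters: without it, average re-referencing makes the
    channel set exactly rank-deficient, which no physical recording is.
    """
    truth = ef.make_var_coefficients(ef.default_coupling_spec(), order=2, seed=0)
    rec = ef.simulate_recording(truth[ef.LOW], duration_s=30.0, seed=42)
    noise = np.random.default_rng(43).standard_normal(rec.data.shape) * 5.0
    return rec.copy_with(rec.data + noise)
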