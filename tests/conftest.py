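import numpy as np
import pytest

from neurophenopipe.ios import IOSMovie, TrialSet


@pytest.fixture
def flat_movie():
    """Noiseless movie identical to its baseline (no stimulus)."""
    frames = np.full((60, 8, 8), 100.0)
    return IOSMovie(frames=frames, fps=30.0, stim_onset_frame=30)


@pytest.fixture
def small_trialset():
    """Ten noiseless identical trials with a known central dip."""
    from neurophenopipe.synthetic import gen_ios_trialset

    return gen_ios_trialset(n_trials=10, shape=(32, 32),
                            evoked_amplitude=0.005, noise_sd=0.0,
                            blob_sigma_px=4.0, seed=0)
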