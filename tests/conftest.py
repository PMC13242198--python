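import numpy as np
import pandas as pd
import pytest

import tacsattn as ta


@pytest.fixture(scope="session")
def default_schedule():
    return ta.generate_schedule(seed=11)


@pytest.fixture(scope="session")
def small_eeg_spec():
    """Reduced channel set (full parieto-occipital ROI plus a few others)."""
    channels = ("Fz", "Cz", "Pz", "P5", "P6", "P7", "P8", "PO3", "PO4",
                "O1", "O2")
    return ta.EEGSpec(channel_names=channels, sampling_rate=256.0)


def make_epochs(data, sampling_rate=256.0, t0=-0.1, channel_names=None,
                alignment="target_onset"):
    """Wrap a (trials, channels, samples) array into EEGEpochs."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    channel_names = tuple(channel_names or
                          [f"ch{i}" for i in range(n_ch)])
    times = t0 + np.arange(n_samp) / sampling_rate
    trials = pd.DataFrame({
        "subject": "S01", "group": "sham", "session": "pre",
        "trial_index": np.arange(n_trials), "cue_type": "endogenous",
        "validity": "valid", "cti_s": 1.0, "trial_type": "Endo-Valid"})
    return ta.EEGEpochs(data=data, times=times, sampling_rate=sampling_rate,
                        alignment=alignment, channel_names=channel_names,
                        trials=trials)


@pytest.fixture()
def make_epochs_fixture():
    return make_epochs
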