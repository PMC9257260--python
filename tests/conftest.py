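import numpy as np
import pytest

from emoconn.preprocessing import EEGRecording, WindowSpec, make_windows
from emoconn.synth import SynthConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-subject synthetic dataset windowed at the default spec."""
    cfg = SynthConfig(n_subjects=2, n_trials=4, duration_s=13.0, seed=7)
    recs, manifest = gen_dataset(cfg)
    lw = make_windows(recs, WindowSpec(3.0, 1.0))
    return cfg, recs, manifest, lw


def sine_recording(freqs, fs=128.0, duration=4.0, amps=None, phases=None,
                   subject=0, trial=0, ratings=(7.0, 3.0, np.nan, np.nan)):
    """Multichannel sum-of-sines test signal."""
    t = np.arange(int(duration * fs)) / fs
    freqs = np.atleast_1d(freqs)
    amps = np.ones(len(freqs)) if amps is None else np.atleast_1d(amps)
    phases = np.zeros(len(freqs)) if phases is None else np.atleast_1d(phases)
    data = np.stack([a * np.sin(2 * np.pi * f * t + p)
                     for f, a, p in zip(freqs, amps, phases)])
    return EEGRecording(data=data, fs=fs, ch_names=[f"CH{i}" for i in range(len(freqs))],
                        subject_id=subject, trial_id=trial, ratings=np.asarray(ratings))
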