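"""Synthetic multi-subject EEG with class-dependent connectivity.

The generator emulates the layout of the DEAP preprocessed distribution
— 32 channels at 128 Hz, 63-s trials whose first 3 s are baseline — with
two controllable phenomena layered on band-limited noise:

* *class signal*: during the post-baseline period, channels in
  ``coupled_set`` mix a shared narrow-band oscillatory source with
  weight kappa (kappa_1 for high-affect trials, kappa_0 otherwise), so
  phase- and amplitude-coupling within the coupled set is stronger for
  the high class.  Half of the coupled channels receive the source
  delayed by ``te_delay`` samples, giving transfer entropy a testable
  direction.
* *domain shift*: each subject draws a gain factor, a noise multiplier,
  a spectral tilt exponent and a background-synchrony level once,
  applied to every trial — emulating inter-subject amplitude, SNR,
  spectral-slope and global-coupling differences that a cross-subject
  classifier must survive.  The background synchrony mixes a per-trial
  common source into *all* channels with subject-specific weight, so a
  subject's whole connectivity matrix is shifted upward without touching
  the class contrast — the information-preserving kind of shift that
  feature alignment can undo.

Ratings are drawn so that the midpoint-5 binarization recovers the
generating class exactly.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .montage import DEAP32_CHANNELS
from .preprocessing import EEGRecording


@dataclass
class SynthConfig:
    n_subjects: int = 4
    n_trials: int = 8                 # per subject, balanced across classes
    n_channels: int = 32
    fs: float = 128.0
    duration_s: float = 63.0          # includes the baseline
    baseline_s: float = 3.0
    coupled_set: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    kappa0: float = 0.3               # low-class coupling strength
    kappa1: float = 0.7               # high-class coupling strength
    carrier_band: tuple[float, float] = (4.0, 45.0)
    noise_band: tuple[float, float] = (4.0, 45.0)
    noise_sd: float = 1.0
    gain_range: tuple[float, float] = (0.6, 1.6)
    noise_mult_range: tuple[float, float] = (0.7, 1.4)
    tilt_range: tuple[float, float] = (-1.5, 1.5)
    bg_coupling_range: tuple[float, float] = (0.0, 0.0)          # optional extra axis
    kappa_offset_range: tuple[float, float] = (-0.2, 0.2)        # per-subject coupling offset
    te_delay: int = 2                 # samples of lag into half the coupled set
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa0 < self.kappa1 <= 1.0:
            raise ValueError("need 0 <= kappa0 < kappa1 <= 1")
        if self.kappa1 + self.bg_coupling_range[1] > 1.0:
            raise ValueError("kappa1 plus maximum background coupling exceeds 1")
        if self.kappa1 + self.kappa_offset_range[1] > 1.0 \
                or self.kappa0 + self.kappa_offset_range[0] < 0.0:
            raise ValueError("kappa offsets push coupling outside [0, 1]")
        if max(self.coupled_set, default=-1) >= self.n_channels:
            raise ValueError("coupled_set outside channel range")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even for balanced classes")
        if self.duration_s <= self.baseline_s:
            raise ValueError("duration must exceed the baseline")

    @property
    def ch_names(self) -> list[str]:
        if self.n_channels == 32:
            return list(DEAP32_CHANNELS)
        return [f"CH{i}" for i in range(self.n_channels)]


def _band_noise(rng: np.random.Generator, band: tuple[float, float], fs: float,
                n: int, n_series: int = 1) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal((n_series, n)), axis=1)
    return x / np.maximum(x.std(axis=1, keepdims=True), 1e-12)


def _apply_tilt(x: np.ndarray, tilt: float, fs: float, f_ref: float = 10.0) -> np.ndarray:
    """Multiply the amplitude spectrum by (f / f_ref)^(tilt/2)."""
    if tilt == 0.0:
        return x
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    w = np.ones_like(f)
    w[1:] = (f[1:] / f_ref) ** (tilt / 2.0)
    return np.fft.irfft(spec * w, n=n, axis=-1)


@dataclass
class SubjectShift:
    gain: float
    noise_mult: float
    tilt: float
    bg_coupling: float
    kappa_offset: float


def _subject_shift(cfg: SynthConfig, subject: int) -> SubjectShift:
    rng = np.random.default_rng([cfg.seed, 1000 + subject])
    return SubjectShift(gain=float(rng.uniform(*cfg.gain_range)),
                        noise_mult=float(rng.uniform(*cfg.noise_mult_range)),
                        tilt=float(rng.uniform(*cfg.tilt_range)),
                        bg_coupling=float(rng.uniform(*cfg.bg_coupling_range)),
                        kappa_offset=float(rng.uniform(*cfg.kappa_offset_range)))


def gen_trial(cfg: SynthConfig, subject: int, class_label: int,
              rng: np.random.Generator, trial_id: int = 0) -> tuple[EEGRecording, float]:
    """One synthetic trial for ``subject`` in class ``class_label`` (0/1).

    Returns the recording (ratings filled so that midpoint binarization
    recovers the class) and the rating actually drawn.
    """
    if class_label not in (0, 1):
        raise ValueError(f"invalid class label {class_label}")
    n = int(round(cfg.duration_s * cfg.fs))
    n_base = int(round(cfg.baseline_s * cfg.fs))
    shift = _subject_shift(cfg, subject)

    noise = _band_noise(rng, cfg.noise_band, cfg.fs, n, cfg.n_channels)
    source = _band_noise(rng, cfg.carrier_band, cfg.fs, n, 1)[0]
    bg = _band_noise(rng, cfg.noise_band, cfg.fs, n, 1)[0]
    # the subject's coupling offset shifts both class levels together:
    # within-subject contrast is preserved while the absolute coupling
    # level differs between subjects
    kappa = (cfg.kappa1 if class_label == 1 else cfg.kappa0) + shift.kappa_offset
    kappa = float(np.clip(kappa, 0.0, 1.0))

    # idiosyncratic noise (scaled by the subject's noise multiplier), a
    # subject-level background source common to all channels, and the
    # class-dependent source on the coupled subset
    kb = shift.bg_coupling
    coupled = sorted(cfg.coupled_set)
    lagged = set(coupled[len(coupled) // 2:])
    kvec = np.zeros(n)
    kvec[n_base:] = kappa  # baseline stays uncoupled
    data = np.empty_like(noise)
    for ch in range(cfg.n_channels):
        kc = kvec if ch in coupled else 0.0
        src = source
        if ch in lagged:
            src = np.roll(source, cfg.te_delay)
        data[ch] = ((1.0 - kc - kb) * shift.noise_mult * noise[ch]
                    + kc * src + kb * bg)

    # per-channel variance normalization: the class signal lives in
    # cross-channel coupling, not in single-channel power
    data = cfg.noise_sd * data / np.maximum(data.std(axis=1, keepdims=True), 1e-12)
    data = _apply_tilt(data, shift.tilt, cfg.fs)
    data *= shift.gain

    rating = float(rng.uniform(6.0, 9.0) if class_label == 1 else rng.uniform(1.0, 5.0))
    ratings = np.array([rating, rating, np.nan, np.nan])  # valence, arousal
    rec = EEGRecording(data=data, fs=cfg.fs, ch_names=cfg.ch_names,
                       subject_id=subject, trial_id=trial_id, ratings=ratings)
    return rec, rating


def gen_dataset(cfg: SynthConfig) -> tuple[list[EEGRecording], dict]:
    """All trials for all subjects plus a manifest of the latents.

    Classes are balanced within each subject; trial order is shuffled
    per subject.  The manifest records, per trial, the class, kappa and
    rating, and per subject the domain-shift latents — enough for
    parameter-recovery tests.
    """
    recordings: list[EEGRecording] = []
    manifest: dict = {"config": {"seed": cfg.seed, "n_subjects": cfg.n_subjects,
                                 "n_trials": cfg.n_trials, "kappa0": cfg.kappa0,
                                 "kappa1": cfg.kappa1},
                      "subjects": {}}
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng([cfg.seed, s])
        classes = np.repeat([0, 1], cfg.n_trials // 2)
        rng.shuffle(classes)
        shift = _subject_shift(cfg, s)
        subj_entry = {"gain": shift.gain, "noise_mult": shift.noise_mult,
                      "tilt": shift.tilt, "bg_coupling": shift.bg_coupling,
                      "kappa_offset": shift.kappa_offset, "trials": []}
        for t, cls in enumerate(classes):
            rec, rating = gen_trial(cfg, s, int(cls), rng, trial_id=t)
            recordings.append(rec)
            kappa = (cfg.kappa1 if cls else cfg.kappa0) + shift.kappa_offset
            subj_entry["trials"].append({"trial": t, "class": int(cls),
                                         "kappa": float(np.clip(kappa, 0.0, 1.0)),
                                         "rating": rating})
        manifest["subjects"][str(s)] = subj_entry
    return recordings, manifest
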