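"""Filtering, baseline trimming, windowing and labelling of EEG recordings.

The processing convention follows the DEAP preprocessed distribution:
63-s trials at 128 Hz whose first 3 s are a pre-stimulus baseline, a
4–45 Hz band-pass, 3-s windows advanced in 0.5-s steps (2.5-s overlap),
and per-trial affect ratings on a 1–9 scale binarized at the midpoint 5
(ratings > 5 are the high class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt, welch

#: Rating columns in DEAP storage order.
RATING_NAMES = ("valence", "arousal", "dominance", "liking")


@dataclass
class EEGRecording:
    """A continuous multichannel EEG trial.

    data is (channels, samples) in microvolts; ``ratings``, when present,
    holds per-trial affect scores on a 1–9 scale in :data:`RATING_NAMES`
    order (missing trailing scores may be NaN).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    subject_id: int | str = 0
    trial_id: int | str = 0
    ratings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError(f"data rows ({self.data.shape[0]}) must match channel names ({len(self.ch_names)})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def rating(self, name: str) -> float:
        if self.ratings is None:
            raise ValueError("recording carries no ratings")
        return float(self.ratings[RATING_NAMES.index(name)])


@dataclass
class WindowSpec:
    """Sliding-window geometry in seconds."""

    length_s: float = 3.0
    step_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError("need 0 < step_s <= length_s")

    def in_samples(self, fs: float) -> tuple[int, int]:
        w = self.length_s * fs
        s = self.step_s * fs
        if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ValueError(f"window ({self.length_s}s) and step ({self.step_s}s) must be whole samples at fs={fs}")
        return int(round(w)), int(round(s))


@dataclass
class LabeledWindows:
    """Windowed dataset with binary labels and full provenance."""

    windows: np.ndarray           # (n, channels, T)
    y_valence: np.ndarray         # (n,) in {0,1}
    y_arousal: np.ndarray         # (n,) in {0,1}
    subject_ids: np.ndarray       # (n,)
    trial_ids: np.ndarray         # (n,)
    starts: np.ndarray            # (n,) window start sample within trial
    fs: float = 128.0
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.windows)
        for name in ("y_valence", "y_arousal", "subject_ids", "trial_ids", "starts"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n windows {n}")
        for y in (self.y_valence, self.y_arousal):
            if y.size and not np.isin(y, (0, 1)).all():
                raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.windows)

    def labels(self, target: str) -> np.ndarray:
        return {"valence": self.y_valence, "arousal": self.y_arousal}[target]

    def select(self, idx: np.ndarray) -> "LabeledWindows":
        return LabeledWindows(self.windows[idx], self.y_valence[idx],
                              self.y_arousal[idx], self.subject_ids[idx],
                              self.trial_ids[idx], self.starts[idx],
                              fs=self.fs, ch_names=self.ch_names)

    def provenance_keys(self) -> set[tuple]:
        """(subject, trial, start) identity of every window."""
        return {(s, t, int(w)) for s, t, w in
                zip(self.subject_ids.tolist(), self.trial_ids.tolist(), self.starts.tolist())}


def bandpass(rec: EEGRecording, lo: float = 4.0, hi: float = 45.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Forward-backward filtering preserves phase relations, which the
    phase-locking estimator downstream depends on.
    """
    if hi >= rec.fs / 2:
        raise ValueError(f"high cutoff {hi} Hz must be below Nyquist {rec.fs / 2} Hz")
    if lo <= 0 or lo >= hi:
        raise ValueError("need 0 < lo < hi")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, data=sosfiltfilt(sos, rec.data, axis=1))


def drop_baseline(rec: EEGRecording, baseline_s: float = 3.0) -> EEGRecording:
    """Remove the first ``baseline_s`` seconds (pre-stimulus) of every channel."""
    n_drop = int(round(baseline_s * rec.fs))
    if n_drop >= rec.n_samples:
        raise ValueError(f"baseline {baseline_s}s consumes the whole {rec.duration_s}s recording")
    return replace(rec, data=rec.data[:, n_drop:])


def segment(rec: EEGRecording, spec: WindowSpec = WindowSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Slice a recording into overlapping windows.

    Returns ``(windows, starts)`` where windows is (n, channels, W) and
    starts are the window start samples; n = floor((L - W)/S) + 1.
    """
    w, s = spec.in_samples(rec.fs)
    if rec.n_samples < w:
        raise ValueError(f"recording ({rec.n_samples} samples) shorter than window ({w})")
    starts = np.arange(0, rec.n_samples - w + 1, s)
    wins = np.stack([rec.data[:, t:t + w] for t in starts])
    return wins, starts


def binarize_rating(r: float) -> int:
    """1–9 affect rating to a binary class: > 5 is high (1), <= 5 low (0)."""
    if not 1.0 <= r <= 9.0:
        raise ValueError(f"rating {r} outside the 1-9 scale")
    return int(r > 5.0)


def compute_psd(window: np.ndarray, fs: float = 128.0,
                band: tuple[float, float] = (4.0, 45.0),
                seg_s: float = 1.0, overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density per channel, restricted to ``band``.

    Returns ``(psd, freqs)`` with psd of shape (channels, n_bins).  Welch
    settings: ``seg_s`` segments, fractional ``overlap``, Hann taper.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    nper = int(round(seg_s * fs))
    if window.shape[1] < nper:
        raise ValueError(f"window of {window.shape[1]} samples shorter than one Welch segment ({nper})")
    freqs, pxx = welch(window, fs=fs, nperseg=nper,
                       noverlap=int(round(nper * overlap)), window="hann", axis=1)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return pxx[:, keep], freqs[keep]


def make_windows(recordings: Iterable[EEGRecording],
                 spec: WindowSpec = WindowSpec(),
                 band: tuple[float, float] | None = (4.0, 45.0),
                 baseline_s: float = 3.0) -> LabeledWindows:
    """Full preprocessing pipeline: band-pass, trim baseline, window, label.

    Windows never cross trial boundaries; every window inherits its
    trial's (subject, trial, rating) provenance.
    """
    wins, yv, ya, subj, trial, starts = [], [], [], [], [], []
    fs = None
    ch_names: list[str] = []
    for rec in recordings:
        fs = rec.fs if fs is None else fs
        if rec.fs != fs:
            raise ValueError("all recordings must share one sampling rate")
        ch_names = rec.ch_names
        r = bandpass(rec, *band) if band is not None else rec
        if baseline_s > 0:
            r = drop_baseline(r, baseline_s)
        w, st = segment(r, spec)
        wins.append(w.astype(np.float32))
        n = len(w)
        yv.append(np.full(n, binarize_rating(rec.rating("valence")), dtype=np.int8))
        ya.append(np.full(n, binarize_rating(rec.rating("arousal")), dtype=np.int8))
        subj.append(np.full(n, rec.subject_id))
        trial.append(np.full(n, rec.trial_id))
        starts.append(st)
    if not wins:
        raise ValueError("no recordings supplied")
    return LabeledWindows(np.concatenate(wins), np.concatenate(yv), np.concatenate(ya),
                          np.concatenate(subj), np.concatenate(trial),
                          np.concatenate(starts), fs=fs, ch_names=ch_names)
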