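"""Per-window brain-connectivity estimators and feature assembly.

Four pairwise measures are supported, each producing an N x N matrix per
EEG window:

* ``pcc`` — Pearson correlation (linear coupling), range [-1, 1];
* ``plv`` — phase-locking value from the analytic (Hilbert) signal,
  range [0, 1]; the window must already be band-passed;
* ``te``  — transfer entropy, a directed plug-in estimate of predictive
  information flow in bits (diagonal 0, matrix asymmetric);
* ``wcc`` — wavelet coherence (complex Morlet CWT with time/scale
  smoothing) averaged over scales and times, range [0, 1].

All estimators are deterministic functions of the input and their
configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .montage import ElectrodeOrder, apply_order
from .preprocessing import LabeledWindows, compute_psd

MEASURES = ("pcc", "plv", "te", "wcc")


@dataclass
class ConnectivityMatrix:
    """An N x N measure-tagged connectivity matrix under a stated order."""

    values: np.ndarray
    measure: str
    order: ElectrodeOrder | None = None
    directed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity values must be square")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_window(window: np.ndarray, min_t: int = 2) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be (channels, samples)")
    if w.shape[1] < min_t:
        raise ValueError(f"window needs at least {min_t} samples")
    return w


def _check_variance(w: np.ndarray) -> None:
    sd = w.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s) {dead.tolist()}: connectivity undefined")


def pcc(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix (1/T moment form, unit diagonal)."""
    w = _check_window(window)
    _check_variance(w)
    t = w.shape[1]
    xc = w - w.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc ** 2).mean(axis=1))
    c = (xc @ xc.T) / t / np.outer(sd, sd)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def instantaneous_phase(window: np.ndarray) -> np.ndarray:
    """Per-channel instantaneous phase of the analytic (Hilbert) signal."""
    w = _check_window(window)
    _check_variance(w)
    return np.angle(hilbert(w, axis=1))


def plv(window: np.ndarray) -> np.ndarray:
    """Phase-locking value: |mean_t exp(i (phi_i - phi_j))|.

    The caller is responsible for band-passing the window first; phases
    of broadband signals are not physiologically interpretable.
    """
    phi = instantaneous_phase(window)
    z = np.exp(1j * phi)
    t = phi.shape[1]
    r = np.abs(z @ z.conj().T) / t
    np.fill_diagonal(r, 1.0)
    return np.clip(r, 0.0, 1.0)


def _equal_frequency_symbols(w: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency discretization (per channel).

    Built on ranks, so the codes are invariant under strictly monotone
    transforms of any channel.
    """
    t = w.shape[1]
    ranks = np.argsort(np.argsort(w, axis=1, kind="stable"), axis=1, kind="stable")
    return (ranks * n_bins) // t


def te(window: np.ndarray, n_bins: int = 8, log_base: float = 2.0) -> np.ndarray:
    """Transfer entropy matrix TE(i -> j) by plug-in estimation.

    Channels are discretized into ``n_bins`` equal-frequency symbols;
    joint occurrences of (s_i^t, s_j^t, s_j^{t+1}) are counted and the
    probability-weighted log-ratio log P(s_j^{t+1}|s_i^t,s_j^t) /
    P(s_j^{t+1}|s_j^t) is summed.  Diagonal is 0 by convention; the
    matrix is generally asymmetric.
    """
    w = _check_window(window, min_t=3)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    t = w.shape[1]
    if n_bins ** 3 > t:
        warnings.warn(f"transfer entropy with {n_bins}^3 states from {t} samples is undersampled")
    s = _equal_frequency_symbols(w, n_bins)
    n_ch = w.shape[0]
    m = t - 1
    out = np.zeros((n_ch, n_ch))
    logb = np.log(log_base)
    for j in range(n_ch):
        sj, sjn = s[j, :-1], s[j, 1:]
        for i in range(n_ch):
            if i == j:
                continue
            code = (s[i, :-1] * n_bins + sj) * n_bins + sjn
            n_abc = np.bincount(code, minlength=n_bins ** 3).reshape(n_bins, n_bins, n_bins)
            n_ab = n_abc.sum(axis=2, keepdims=True)
            n_bc = n_abc.sum(axis=0, keepdims=True)
            n_b = n_abc.sum(axis=(0, 2), keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.log((n_abc * n_b) / (n_ab * n_bc)) / logb
            mask = n_abc > 0
            out[i, j] = float((n_abc[mask] / m * ratio[mask]).sum())
    return np.clip(out, 0.0, None)


def _morlet_scales(fs: float, f_lo: float, f_hi: float, n_scales: int,
                   wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    fc = pywt.central_frequency(wavelet)
    freqs = np.geomspace(f_lo, f_hi, n_scales)
    return fc * fs / freqs, freqs


def wcc(window: np.ndarray, fs: float = 128.0, f_lo: float = 4.0, f_hi: float = 45.0,
        n_scales: int = 24, wavelet: str = "cmor1.0-0.955",
        time_smooth: float = 0.6, scale_smooth: int = 3) -> np.ndarray:
    """Wavelet-coherence matrix averaged over scales and times.

    Complex Morlet CWT on a log-spaced scale grid covering
    [``f_lo``, ``f_hi``] Hz; cross- and auto-spectra are smoothed by a
    Gaussian in time (sigma = ``time_smooth`` x scale, in samples) and a
    ``scale_smooth``-point boxcar across scales before forming
    |S_xy|^2 / (S_xx S_yy).  The final scalar per pair is the mean over
    all (scale, time) points; the diagonal is exactly 1.
    """
    w = _check_window(window)
    _check_variance(w)
    n_ch, t = w.shape
    scales, freqs = _morlet_scales(fs, f_lo, f_hi, n_scales, wavelet)
    if scales.size == 0:
        raise ValueError("empty scale grid")
    if t < fs / f_lo:
        raise ValueError("window shorter than one cycle of the lowest frequency")
    coeffs, _ = pywt.cwt(w, scales, wavelet, axis=1)  # (n_scales, n_ch, t)
    cross = np.empty((n_scales, n_ch, n_ch, t), dtype=complex)
    power = np.empty((n_scales, n_ch, t))
    for k, sc in enumerate(scales):
        c = coeffs[k]
        xy = c[:, None, :] * c.conj()[None, :, :]
        sig = max(time_smooth * sc, 1e-6)
        cross[k] = gaussian_filter1d(xy.real, sig, axis=-1) + 1j * gaussian_filter1d(xy.imag, sig, axis=-1)
        power[k] = gaussian_filter1d((np.abs(c) ** 2), sig, axis=-1)
    if scale_smooth > 1:
        cross = (uniform_filter1d(cross.real, scale_smooth, axis=0, mode="nearest")
                 + 1j * uniform_filter1d(cross.imag, scale_smooth, axis=0, mode="nearest"))
        power = uniform_filter1d(power, scale_smooth, axis=0, mode="nearest")
    denom = power[:, :, None, :] * power[:, None, :, :]
    coh = (np.abs(cross) ** 2) / np.maximum(denom, 1e-300)
    out = coh.mean(axis=(0, 3))
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


_MEASURE_FNS = {"pcc": pcc, "plv": plv, "te": te, "wcc": wcc}


def connectivity_matrix(window: np.ndarray, measure: str,
                        order: ElectrodeOrder | None = None,
                        **kwargs) -> ConnectivityMatrix:
    """One window to one measure-tagged (optionally reordered) matrix."""
    if measure not in _MEASURE_FNS:
        raise ValueError(f"unknown measure {measure!r}; pick from {MEASURES}")
    vals = _MEASURE_FNS[measure](window, **kwargs)
    cm = ConnectivityMatrix(vals, measure=measure, directed=measure == "te")
    if order is not None:
        cm = apply_order(cm, order)
    return cm


def build_features(dataset: LabeledWindows, measure: str,
                   order: ElectrodeOrder | None = None,
                   **kwargs) -> np.ndarray:
    """Per-window connectivity tensor (n, N, N) under the given order."""
    n = len(dataset)
    n_ch = dataset.windows.shape[1] if n else 0
    out = np.empty((n, n_ch, n_ch), dtype=np.float32)
    fn = _MEASURE_FNS[measure]
    for k in range(n):
        out[k] = fn(dataset.windows[k], **kwargs)
    if order is not None:
        out = out[:, order.perm][:, :, order.perm]
    return out


class ConnectivityTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: (n, channels, T) windows to (n, N, N) matrices.

    Parameters
    ----------
    measure : one of "pcc", "plv", "te", "wcc".
    order : optional ElectrodeOrder applied to rows and columns.
    fs : sampling rate, used by the wavelet-coherence measure.
    te_bins : number of equal-frequency bins for transfer entropy.
    """

    def __init__(self, measure: str = "plv", order: ElectrodeOrder | None = None,
                 fs: float = 128.0, te_bins: int = 8):
        self.measure = measure
        self.order = order
        self.fs = fs
        self.te_bins = te_bins

    def fit(self, X, y=None):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X)
        kwargs = {}
        if self.measure == "te":
            kwargs["n_bins"] = self.te_bins
        elif self.measure == "wcc":
            kwargs["fs"] = self.fs
        fn = _MEASURE_FNS[self.measure]
        out = np.empty((len(X), X.shape[1], X.shape[1]), dtype=np.float32)
        for k in range(len(X)):
            out[k] = fn(X[k], **kwargs)
        if self.order is not None:
            out = out[:, self.order.perm][:, :, self.order.perm]
        return out


class PSDTransformer(TransformerMixin, BaseEstimator):
    """Welch log-power features: (n, channels, T) windows to (n, channels, bins)."""

    def __init__(self, fs: float = 128.0, band: tuple[float, float] = (4.0, 45.0),
                 seg_s: float = 1.0, overlap: float = 0.5, log: bool = True):
        self.fs = fs
        self.band = band
        self.seg_s = seg_s
        self.overlap = overlap
        self.log = log

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        first, _ = compute_psd(X[0], fs=self.fs, band=self.band,
                               seg_s=self.seg_s, overlap=self.overlap)
        out = np.empty((len(X),) + first.shape, dtype=np.float32)
        out[0] = first
        for k in range(1, len(X)):
            out[k], _ = compute_psd(X[k], fs=self.fs, band=self.band,
                                    seg_s=self.seg_s, overlap=self.overlap)
        if self.log:
            out = np.log10(np.maximum(out, 1e-20, dtype=np.float64)).astype(np.float32)
        return out
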