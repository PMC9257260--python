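"""Readers and writers: DEAP-style subject files, EDF/BDF, HDF5 interchange.

The internal interchange format is HDF5 throughout (window tensors get
large); CSV/JSON appear only at the edges.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import h5py
import numpy as np

from .preprocessing import EEGRecording, LabeledWindows

DEAP_SHAPE = (40, 40, 8064)
DEAP_N_EEG = 32


def read_deap_subject(path: str | Path, ch_names: list[str] | None = None,
                      rating_order: tuple[str, ...] | None = None) -> list[EEGRecording]:
    """Read one DEAP-style preprocessed subject file.

    Accepts ``.npz``/``.h5``/``.hdf5`` with arrays ``data`` (40 x 40 x 8064)
    and ``labels`` (40 x 4), or the pickled ``.dat`` distribution format
    with the same keys.  Only the first 32 rows (EEG channels) are kept;
    rating columns are (valence, arousal, dominance, liking) unless
    ``rating_order`` overrides the stored order.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            data, labels = f["data"], f["labels"]
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data, labels = f["data"][()], f["labels"][()]
    else:
        with open(path, "rb") as fh:
            d = pickle.load(fh, encoding="latin1")
        data, labels = np.asarray(d["data"]), np.asarray(d["labels"])
    if data.shape != DEAP_SHAPE:
        raise ValueError(f"expected data shape {DEAP_SHAPE}, found {data.shape}")
    if labels.shape != (DEAP_SHAPE[0], 4):
        raise ValueError(f"expected ratings shape {(DEAP_SHAPE[0], 4)}, found {labels.shape}")
    if ch_names is None:
        from .montage import DEAP32_CHANNELS
        ch_names = list(DEAP32_CHANNELS)
    subject = path.stem
    recs = []
    for t in range(DEAP_SHAPE[0]):
        ratings = np.asarray(labels[t], dtype=float)
        if rating_order is not None:
            from .preprocessing import RATING_NAMES
            ratings = ratings[[rating_order.index(n) for n in RATING_NAMES]]
        recs.append(EEGRecording(data=data[t, :DEAP_N_EEG], fs=128.0,
                                 ch_names=ch_names, subject_id=subject,
                                 trial_id=t, ratings=ratings))
    return recs


def write_deap_subject(path: str | Path, data: np.ndarray, labels: np.ndarray) -> None:
    """Write a DEAP-layout ``.npz`` fixture (shape-checked)."""
    data, labels = np.asarray(data), np.asarray(labels)
    if data.shape != DEAP_SHAPE or labels.shape != (DEAP_SHAPE[0], 4):
        raise ValueError(f"refusing to write non-DEAP shapes {data.shape}, {labels.shape}")
    np.savez_compressed(path, data=data, labels=labels)


def read_edf(path: str | Path, subject_id=0, trial_id=0) -> EEGRecording:
    """Read an EDF/BDF recording into an EEGRecording (all channels, volts->uV)."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    return EEGRecording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names), subject_id=subject_id,
                        trial_id=trial_id)


# ---------------------------------------------------------------------------
# HDF5 interchange


def save_recordings(path: str | Path, recordings: list[EEGRecording],
                    manifest: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        if manifest is not None:
            f.attrs["manifest"] = json.dumps(manifest)
        for k, rec in enumerate(recordings):
            g = f.create_group(f"rec{k:05d}")
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.attrs["fs"] = rec.fs
            g.attrs["ch_names"] = json.dumps(rec.ch_names)
            g.attrs["subject_id"] = str(rec.subject_id)
            g.attrs["trial_id"] = str(rec.trial_id)
            if rec.ratings is not None:
                g.create_dataset("ratings", data=rec.ratings)


def load_recordings(path: str | Path) -> tuple[list[EEGRecording], dict | None]:
    recs = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"]) if "manifest" in f.attrs else None
        for key in sorted(f.keys()):
            g = f[key]
            sid, tid = g.attrs["subject_id"], g.attrs["trial_id"]
            recs.append(EEGRecording(
                data=g["data"][()], fs=float(g.attrs["fs"]),
                ch_names=json.loads(g.attrs["ch_names"]),
                subject_id=int(sid) if sid.isdigit() else sid,
                trial_id=int(tid) if tid.isdigit() else tid,
                ratings=g["ratings"][()] if "ratings" in g else None))
    return recs, manifest


def save_windows(path: str | Path, lw: LabeledWindows) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=lw.windows, compression="gzip")
        for name in ("y_valence", "y_arousal", "starts"):
            f.create_dataset(name, data=getattr(lw, name))
        for name in ("subject_ids", "trial_ids"):
            f.create_dataset(name, data=np.asarray(getattr(lw, name), dtype="S32"))
        f.attrs["fs"] = lw.fs
        f.attrs["ch_names"] = json.dumps(lw.ch_names)


def _decode_ids(arr: np.ndarray) -> np.ndarray:
    vals = [v.decode() for v in arr]
    if all(v.lstrip("-").isdigit() for v in vals):
        return np.array([int(v) for v in vals])
    return np.array(vals, dtype=object)


def load_windows(path: str | Path) -> LabeledWindows:
    with h5py.File(path, "r") as f:
        return LabeledWindows(
            windows=f["windows"][()], y_valence=f["y_valence"][()],
            y_arousal=f["y_arousal"][()],
            subject_ids=_decode_ids(f["subject_ids"][()]),
            trial_ids=_decode_ids(f["trial_ids"][()]),
            starts=f["starts"][()], fs=float(f.attrs["fs"]),
            ch_names=json.loads(f.attrs["ch_names"]))


def save_features(path: str | Path, features: np.ndarray, lw: LabeledWindows,
                  measure: str, order_labels: list[str] | None = None,
                  config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features, compression="gzip")
        f.create_dataset("y_valence", data=lw.y_valence)
        f.create_dataset("y_arousal", data=lw.y_arousal)
        f.create_dataset("subject_ids", data=np.asarray(lw.subject_ids, dtype="S32"))
        f.create_dataset("trial_ids", data=np.asarray(lw.trial_ids, dtype="S32"))
        f.create_dataset("starts", data=lw.starts)
        f.attrs["measure"] = measure
        if order_labels is not None:
            f.attrs["order"] = json.dumps(order_labels)
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def load_features(path: str | Path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        feats = f["features"][()]
        meta = {"measure": f.attrs.get("measure"),
                "y_valence": f["y_valence"][()], "y_arousal": f["y_arousal"][()],
                "subject_ids": _decode_ids(f["subject_ids"][()]),
                "trial_ids": _decode_ids(f["trial_ids"][()]),
                "starts": f["starts"][()]}
        if "order" in f.attrs:
            meta["order"] = json.loads(f.attrs["order"])
        if "config" in f.attrs:
            meta["config"] = json.loads(f.attrs["config"])
    return feats, meta
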