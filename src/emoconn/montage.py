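"""Electrode layouts and distance-based electrode orderings.

Connectivity matrices are arranged under an explicit electrode order so
that spatially (or functionally) close channels sit in adjacent rows and
columns.  The reference ordering for the 32-channel DEAP layout is a
greedy nearest-neighbour chain over the scalp starting from the left
frontal pole; the exact published chain ships as
:data:`DEAP32_DIST_ORDER` and is what ``dist``-mode resolves to for the
bundled montage, so downstream stages do not depend on reproducing the
chain from any particular coordinate table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: DEAP preprocessed-channel order (Geneva convention, first 32 channels).
DEAP32_CHANNELS = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4", "F8", "FC6",
    "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

#: Canonical distance-mode chain for the DEAP 32-channel cap.
DEAP32_DIST_ORDER = [
    "Fp1", "AF3", "F3", "F7", "FC5", "T7", "CP5", "P7", "P3", "PO3", "O1",
    "Oz", "O2", "PO4", "P4", "P8", "CP6", "T8", "FC6", "F8", "F4", "AF4",
    "Fp2", "Fz", "FC1", "C3", "CP1", "Pz", "CP2", "C4", "FC2", "Cz",
]


@dataclass
class Montage:
    """Electrode names with 2-D projected scalp-plane positions."""

    labels: list[str]
    coords: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (N, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None


@dataclass
class ElectrodeOrder:
    """A permutation of channel indices 0..N-1 with its construction mode."""

    perm: np.ndarray
    mode: str = "custom"
    labels: list[str] | None = None
    stress: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.perm = np.asarray(self.perm, dtype=int)
        n = len(self.perm)
        if not np.array_equal(np.sort(self.perm), np.arange(n)):
            raise ValueError("perm must be a bijection on 0..N-1")

    def __len__(self) -> int:
        return len(self.perm)

    def ordered_labels(self) -> list[str]:
        if self.labels is None:
            raise ValueError("order carries no electrode labels")
        return [self.labels[i] for i in self.perm]

    def inverse(self) -> "ElectrodeOrder":
        inv = np.empty_like(self.perm)
        inv[self.perm] = np.arange(len(self.perm))
        return ElectrodeOrder(inv, mode="custom", labels=self.labels)


def load_deap32_montage() -> Montage:
    """The bundled 32-channel layout (azimuthal-equidistant 2-D projection)."""
    ref = importlib.resources.files("emoconn.data") / "deap32_montage.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return Montage(labels=df["label"].tolist(), coords=df[["x", "y"]].to_numpy())


def order_by_distance(montage: Montage, start: str) -> ElectrodeOrder:
    """Greedy nearest-unvisited-neighbour chain beginning at ``start``.

    At each step the electrode closest (Euclidean, in the montage plane)
    to the current one among those not yet visited is appended.  Distance
    ties break by ascending electrode label.
    """
    cur = montage.index(start)
    n = len(montage)
    remaining = set(range(n)) - {cur}
    chain = [cur]
    while remaining:
        rem = sorted(remaining, key=lambda i: montage.labels[i])
        d = np.linalg.norm(montage.coords[rem] - montage.coords[cur], axis=1)
        cur = rem[int(np.argmin(d))]  # argmin keeps the first (lowest label) on ties
        chain.append(cur)
        remaining.remove(cur)
    return ElectrodeOrder(np.array(chain), mode="dist", labels=montage.labels)


def canonical_dist_order(ch_names: list[str] | None = None) -> ElectrodeOrder:
    """The published DEAP-32 distance chain as an order over ``ch_names``.

    ``ch_names`` defaults to the DEAP channel convention; it must contain
    exactly the 32 electrodes of the chain.
    """
    names = list(ch_names) if ch_names is not None else list(DEAP32_CHANNELS)
    if sorted(names) != sorted(DEAP32_DIST_ORDER):
        raise ValueError("channel names do not match the DEAP 32-electrode set")
    perm = np.array([names.index(ch) for ch in DEAP32_DIST_ORDER])
    return ElectrodeOrder(perm, mode="dist", labels=names)


def apply_order(matrix, order: ElectrodeOrder):
    """Permute rows and columns of a square (connectivity) matrix identically.

    Accepts a plain ndarray or a ConnectivityMatrix; the measure tag and
    directedness are preserved.
    """
    from .connectivity import ConnectivityMatrix  # cycle guard

    if isinstance(matrix, ConnectivityMatrix):
        vals = apply_order(matrix.values, order)
        return ConnectivityMatrix(values=vals, measure=matrix.measure,
                                  directed=matrix.directed, order=order)
    matrix = np.asarray(matrix)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != len(order.perm):
        raise ValueError(f"matrix shape {matrix.shape} does not match order of length {len(order.perm)}")
    return matrix[np.ix_(order.perm, order.perm)]
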