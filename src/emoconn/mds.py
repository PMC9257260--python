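"""One-dimensional scaling (UDS) electrode ordering.

Given a symmetric connectivity matrix ``c``, electrodes are embedded on a
line by minimizing the normalized stress

    stress(l_1..l_N) = sum_{i<j} (|l_i - l_j| - delta(i,j))^2
                       / sum_{i<j} delta(i,j)^2

where the disparity ``delta`` encodes the target arrangement:

* ``global`` mode: delta = 2 (1 - c) — strongly connected electrodes are
  pulled together, building a globally smooth arrangement (an optional
  ``sqrt_disparity`` flag uses the conventional sqrt(2(1-c)) form);
* ``local`` mode: delta = c^2 — strongly connected electrodes are pushed
  apart, concentrating local contrast.

The embedding's metric information is discarded; only the rank order of
the coordinates is kept.  The stress landscape is multimodal, so the
minimization is multi-start (seeded) local optimization keeping the best
of ``restarts`` runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .montage import ElectrodeOrder


@dataclass
class UDSState:
    """Result of a 1-D scaling run: disparities, embedding, stress, seed."""

    delta: np.ndarray        # (N, N) non-negative symmetric disparities
    embedding: np.ndarray    # (N,) scalar coordinates of the best restart
    stress: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.delta < 0) or np.any(np.diag(self.delta) != 0):
            raise ValueError("disparities must be non-negative with zero diagonal")
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def disparities(conn: np.ndarray, mode: str, sqrt_disparity: bool = False) -> np.ndarray:
    """Disparity matrix for UDS ordering; diagonal forced to zero."""
    c = np.asarray(conn, dtype=float)
    if mode == "global":
        d = 2.0 * (1.0 - c)
        if sqrt_disparity:
            d = np.sqrt(np.clip(d, 0.0, None))
    elif mode == "local":
        d = c ** 2
    else:
        raise ValueError(f"unknown UDS mode {mode!r}")
    np.fill_diagonal(d, 0.0)
    return d


def stress(embedding: np.ndarray, delta: np.ndarray) -> float:
    """Normalized stress of a 1-D embedding against a disparity matrix."""
    l = np.asarray(embedding, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = len(l)
    if delta.shape != (n, n):
        raise ValueError("embedding and disparity dimensions differ")
    iu = np.triu_indices(n, k=1)
    denom = float((delta[iu] ** 2).sum())
    if denom == 0.0:
        raise ValueError("all-zero disparities: stress undefined")
    diff = np.abs(l[:, None] - l[None, :]) - delta
    return float((diff[iu] ** 2).sum() / denom)


def _stress_and_grad(l: np.ndarray, delta: np.ndarray, denom: float):
    d = l[:, None] - l[None, :]
    ad = np.abs(d)
    r = ad - delta
    val = (r ** 2).sum() / (2.0 * denom)  # full matrix double-counts pairs
    g = 2.0 * r * np.sign(d)
    grad = g.sum(axis=1) / denom
    return val, grad


def uds_embed(conn: np.ndarray, mode: str, seed: int = 0, restarts: int = 20,
              sqrt_disparity: bool = False, symmetrize: str = "mean") -> UDSState:
    """Best 1-D stress embedding of a connectivity matrix.

    Directed matrices are symmetrized as (M + M.T)/2 when ``symmetrize``
    is ``"mean"`` (with a warning), or rejected with ``"error"``.
    Reproducible given (seed, restarts).
    """
    c = np.asarray(conn, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(c, c.T, atol=1e-12):
        if symmetrize == "mean":
            warnings.warn("asymmetric connectivity symmetrized as (M + M.T)/2 for ordering")
            c = 0.5 * (c + c.T)
        else:
            raise ValueError("connectivity matrix must be symmetric")
    delta = disparities(c, mode, sqrt_disparity=sqrt_disparity)
    n = c.shape[0]
    iu = np.triu_indices(n, k=1)
    denom = float((delta[iu] ** 2).sum())
    if denom == 0.0:
        raise ValueError("all-zero disparities: ordering undefined")

    rng = np.random.default_rng(seed)
    scale = max(delta.max(), 1e-12)
    best_l, best_s = None, np.inf
    for _ in range(max(1, restarts)):
        l0 = rng.uniform(-scale, scale, size=n)
        res = minimize(_stress_and_grad, l0, args=(delta, denom), jac=True,
                       method="L-BFGS-B")
        s = stress(res.x, delta)
        if s < best_s - 1e-15:
            best_s, best_l = s, res.x
    return UDSState(delta=delta, embedding=best_l, stress=best_s, seed=seed)


def uds_order(conn: np.ndarray, mode: str, seed: int = 0, restarts: int = 20,
              sqrt_disparity: bool = False, symmetrize: str = "mean",
              labels: list[str] | None = None) -> ElectrodeOrder:
    """Rank order of the best 1-D stress embedding of a connectivity matrix.

    The embedding's metric information is discarded; the order is
    canonicalized against the reflection symmetry so that the
    first-listed electrode index is smaller than the last.
    """
    state = uds_embed(conn, mode, seed=seed, restarts=restarts,
                      sqrt_disparity=sqrt_disparity, symmetrize=symmetrize)
    perm = np.argsort(state.embedding, kind="stable")
    if perm[0] > perm[-1]:  # reflection-invariant canonical form
        perm = perm[::-1].copy()
    return ElectrodeOrder(perm, mode=mode, labels=labels, stress=state.stress)
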