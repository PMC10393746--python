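"""Unsupervised analysis: hierarchical clustering and consensus NMF.

NMF uses multiplicative Kullback-Leibler updates with seeded random
restarts; consensus clustering aggregates co-membership over restarts and
cuts a hierarchical tree on 1 - consensus.  Input features are min-max
shifted to [0, 1] because standardized spatial statistics can be negative
(see :func:`nonnegative_scale`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "hierarchical_clusters",
    "nonnegative_scale",
    "nmf_factorize",
    "consensus_cluster",
    "top_contributing_features",
    "NMFResult",
    "ConsensusResult",
]

_EPS = 1e-12


def hierarchical_clusters(matrix: pd.DataFrame | np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage clustering with 1 - Pearson correlation distance.

    Rows are observations (patients).  Returns integer labels in 1..k.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} observations")
    sd = X.std(axis=1)
    if (sd == 0).any():
        idx = np.flatnonzero(sd == 0)
        names = (
            [str(matrix.index[i]) for i in idx]
            if isinstance(matrix, pd.DataFrame)
            else [str(i) for i in idx]
        )
        raise ValueError(
            f"constant profile(s) make correlation undefined: {names}"
        )
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def nonnegative_scale(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-feature (column) min-max scaling to [0, 1]; constant columns -> 0."""
    X = np.asarray(matrix, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


@dataclass
class NMFResult:
    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    error: float  # final KL divergence
    errors: list[float] = field(default_factory=list)  # tracked every 10 iters
    n_iter: int = 0

    def labels(self) -> np.ndarray:
        """Cluster per sample = argmax coefficient (ties -> lowest index)."""
        return self.H.argmax(axis=0)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float(
        (V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum()
    )


def nmf_factorize(
    matrix: np.ndarray,
    k: int,
    n_iter: int = 2000,
    seed: int = 0,
    tol: float = 1e-5,
) -> NMFResult:
    """Multiplicative KL-divergence NMF (features x samples = W @ H).

    Updates::

        H <- H * (W' (V / WH)) / (W' 1)
        W <- W * ((V / WH) H') / (1 H')

    The KL objective is non-increasing under these updates; iteration stops
    when the relative error change over 10 iterations drops below ``tol``.
    """
    V = np.asarray(matrix, dtype=float)
    if (V < 0).any():
        raise ValueError(
            "NMF input must be non-negative; scale features first "
            "(e.g. spatialtme.unsupervised.nonnegative_scale)"
        )
    if not 1 <= k < min(V.shape):
        raise ValueError(f"k={k} must be in [1, min{V.shape})")
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    W = rng.uniform(_EPS, scale, size=(V.shape[0], k))
    H = rng.uniform(_EPS, scale, size=(k, V.shape[1]))
    errors: list[float] = []
    prev = np.inf
    it = 0
    for it in range(1, n_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        if it % 10 == 0 or it == n_iter:
            err = _kl_divergence(V, W @ H + _EPS)
            errors.append(err)
            if np.isfinite(prev) and abs(prev - err) <= tol * max(abs(prev), 1.0):
                prev = err
                break
            prev = err
    return NMFResult(W=W, H=H, error=errors[-1], errors=errors, n_iter=it)


@dataclass
class ConsensusResult:
    k: int
    labels: np.ndarray  # 1..k per sample
    consensus: np.ndarray  # samples x samples, in [0, 1]
    cophenetic: float
    runs: list[NMFResult]
    top_features: dict[int, list[int]] = field(default_factory=dict)

    @property
    def W(self) -> np.ndarray:
        """Basis of the best (lowest-error) run."""
        return min(self.runs, key=lambda r: r.error).W


def consensus_cluster(
    matrix: np.ndarray,
    k: int,
    n_runs: int = 20,
    n_iter: int = 2000,
    seed: int = 0,
    top_threshold: float = 0.8,
) -> ConsensusResult:
    """Consensus NMF: co-membership frequency over seeded restarts.

    Final labels come from average-linkage hierarchical clustering of
    1 - consensus; the cophenetic correlation of that tree against
    1 - consensus measures cluster stability.
    """
    if k < 2:
        raise ValueError("consensus clustering needs k >= 2")
    V = np.asarray(matrix, dtype=float)
    n = V.shape[1]
    ss = np.random.SeedSequence(seed)
    runs = [
        nmf_factorize(V, k, n_iter=n_iter, seed=int(child.generate_state(1)[0]))
        for child in ss.spawn(n_runs)
    ]
    consensus = np.zeros((n, n))
    for res in runs:
        lab = res.labels()
        consensus += (lab[:, None] == lab[None, :]).astype(float)
    consensus /= n_runs
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if condensed.std() == 0:
        coph = 1.0  # degenerate: all distances equal, tree is exact
    else:
        coph = float(cophenet(Z, condensed)[0])
    W_best = min(runs, key=lambda r: r.error).W
    top = top_contributing_features(W_best, threshold=top_threshold)
    return ConsensusResult(
        k=k,
        labels=labels,
        consensus=consensus,
        cophenetic=coph,
        runs=runs,
        top_features=top,
    )


def top_contributing_features(
    W: np.ndarray, threshold: float = 0.8
) -> dict[int, list[int]]:
    """Per basis column: feature indices with contribution >= threshold * max."""
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("basis matrix must be non-negative")
    out: dict[int, list[int]] = {}
    for col in range(W.shape[1]):
        w = W[:, col]
        mx = w.max()
        if mx <= 0:
            warnings.warn(f"basis column {col} is all zero; no top features")
            out[col] = []
            continue
        out[col] = [int(i) for i in np.flatnonzero(w >= threshold * mx)]
    return out
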