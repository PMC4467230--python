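"""Evoked responses: global field power and cluster permutation statistics.

Component windows are located on the global field power (the SD across
channels of the evoked response at each sample), and condition
contrasts are tested with a paired cluster-based permutation test:
supra-threshold (channel, sample) points are joined into
spatio-temporal clusters via channel adjacency plus temporal
contiguity, each cluster's mass is the sum of its t values, and the
null distribution of the maximal cluster mass is built by sign-flipping
the per-replicate condition differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.signal import find_peaks

from .epochs import EpochSet

__all__ = [
    "Evoked",
    "ClusterResult",
    "evoked_from_epochs",
    "global_field_power",
    "component_windows",
    "knn_adjacency",
    "cluster_permutation_test",
]


@dataclass
class Evoked:
    """Channels x time average over trials for one condition/replicate."""

    data: np.ndarray
    times: np.ndarray
    channels: pd.DataFrame
    condition: str = ""
    n_trials: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("an evoked response needs at least one trial")
        if self.data.shape != (len(self.channels), len(self.times)):
            raise ValueError("evoked data must be channels x time")


def evoked_from_epochs(epochs: EpochSet, trial_mask, condition: str = "") -> Evoked:
    mask = np.asarray(trial_mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"condition '{condition}' selects no trials")
    return Evoked(epochs.data[mask].mean(axis=0), epochs.times.copy(),
                  epochs.channels.copy(), condition, int(mask.sum()))


def global_field_power(evoked: Evoked) -> np.ndarray:
    """Across-channel SD of the evoked values at each time sample."""
    if evoked.data.shape[0] < 2:
        raise ValueError("global field power needs at least 2 channels")
    return evoked.data.std(axis=0, ddof=0)


def component_windows(
    gfp: np.ndarray,
    times: np.ndarray,
    widths_ms: tuple[float, ...] = (36.0, 300.0),
    after_ms: float = 150.0,
) -> list[tuple[float, float]]:
    """Windows centred on the highest GFP lobes after ``after_ms``.

    With the default widths this reproduces the canonical N2-like
    (36 ms) and P3-like (300 ms) analysis windows; one window is
    returned per entry of ``widths_ms``, ordered by peak height.
    """
    times = np.asarray(times)
    sel = times >= after_ms
    g = np.asarray(gfp)[sel]
    t = times[sel]
    peaks, _ = find_peaks(g)
    if peaks.size < len(widths_ms):  # fall back to the highest samples
        peaks = np.argsort(g)[::-1][: len(widths_ms)]
    order = peaks[np.argsort(g[peaks])[::-1]][: len(widths_ms)]
    return [(t[p] - w / 2, t[p] + w / 2) for p, w in zip(order, widths_ms)]


def knn_adjacency(n_channels: int, k: int = 4, seed: int = 0):
    """Symmetric k-nearest-neighbour channel graph on random 2-D sensor positions.

    Components are bridged through their closest cross pair so the
    graph is always connected.  Returns (coords, csr boolean adjacency).
    """
    rng = np.random.default_rng(seed)
    coords = rng.random((n_channels, 2))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    nn = np.argsort(d, axis=1)[:, :k]
    for i in range(n_channels):
        adj[i, nn[i]] = True
    adj |= adj.T
    # bridge disconnected components (rare for k >= 4)
    while True:
        n_comp, lab = connected_components(sparse.csr_matrix(adj), directed=False)
        if n_comp == 1:
            break
        a = lab == lab[0]
        sub = d[np.ix_(a, ~a)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        ia, ja = np.flatnonzero(a)[i], np.flatnonzero(~a)[j]
        adj[ia, ja] = adj[ja, ia] = True
    return coords, sparse.csr_matrix(adj)


@dataclass
class ClusterResult:
    """Observed spatio-temporal clusters and their permutation p-values."""

    clusters: list = field(default_factory=list)
    n_permutations: int = 0
    forming_threshold: float = np.nan
    df: int = 0


def _lattice(adjacency: sparse.csr_matrix, n_samples: int) -> sparse.csr_matrix:
    """Adjacency of the (channel, sample) lattice: spatial + temporal neighbours."""
    n_ch = adjacency.shape[0]
    eye_t = sparse.eye(n_samples, format="csr", dtype=bool)
    spatial = sparse.kron(adjacency.astype(bool), eye_t, format="csr")
    temporal_1d = sparse.diags([np.ones(n_samples - 1)], [1], format="csr", dtype=bool)
    temporal = sparse.kron(sparse.eye(n_ch, dtype=bool), temporal_1d + temporal_1d.T, format="csr")
    return ((spatial + temporal) > 0).tocsr()


def _clusters_of(tmap: np.ndarray, thr: float, lattice: sparse.csr_matrix):
    """All supra-threshold clusters (both signs) of a flattened t-map."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * tmap > thr
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = lattice[idx][:, idx]
        n_comp, lab = connected_components(sub, directed=False)
        for c in range(n_comp):
            nodes = idx[lab == c]
            out.append((nodes, float(tmap[nodes].sum())))
    return out


def cluster_permutation_test(
    evoked_a: list[Evoked],
    evoked_b: list[Evoked],
    window_ms: tuple[float, float],
    adjacency: sparse.csr_matrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    forming_p: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Paired cluster test of condition A vs B evoked responses.

    The per-(channel, sample) statistic is a paired t across replicates;
    the cluster-forming threshold is the two-tailed t critical value at
    ``forming_p``; cluster mass is the sum of t; the null is the maximal
    absolute cluster mass over ``n_perm`` random sign flips of the
    replicate differences, giving p = (1 + #null >= observed)/(1 + n_perm).
    """
    if len(evoked_a) != len(evoked_b) or len(evoked_a) < 2:
        raise ValueError("paired replicate lists of equal length (>= 2) required")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value", RuntimeWarning)
    n_ch = adjacency.shape[0]
    if connected_components(adjacency, directed=False)[0] != 1:
        raise ValueError("channel adjacency graph is disconnected")

    times = evoked_a[0].times
    smask = (times >= window_ms[0]) & (times < window_ms[1])
    diffs = np.stack([a.data[:, smask] - b.data[:, smask] for a, b in zip(evoked_a, evoked_b)])
    n_rep, _, n_s = diffs.shape
    if diffs.shape[1] != n_ch:
        raise ValueError("adjacency does not cover all channels")
    df = n_rep - 1
    thr = float(stats.t.ppf(1 - forming_p / 2, df))
    lattice = _lattice(adjacency, n_s)

    flat = diffs.reshape(n_rep, -1)
    sumsq = (flat**2).sum(axis=0)

    def tmap_for(signs: np.ndarray) -> np.ndarray:
        m = signs @ flat / n_rep
        var = np.maximum(sumsq / n_rep - m**2, 0.0) * n_rep / df
        with np.errstate(divide="ignore", invalid="ignore"):
            return m / np.sqrt(var / n_rep)

    observed = _clusters_of(tmap_for(np.ones(n_rep)), thr, lattice)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_rep)
        perm_clusters = _clusters_of(tmap_for(signs), thr, lattice)
        if perm_clusters:
            null_max[p] = max(abs(m) for _, m in perm_clusters)

    clusters = []
    w_times = times[smask]
    for nodes, mass in observed:
        ch = np.unique(nodes // n_s)
        samp = np.unique(nodes % n_s)
        pval = float((1 + (null_max >= abs(mass)).sum()) / (1 + n_perm))
        clusters.append(
            {"channels": ch.tolist(), "time_window": (float(w_times[samp.min()]), float(w_times[samp.max()])),
             "mass": mass, "p": pval, "significant": pval <= alpha}
        )
    clusters.sort(key=lambda c: abs(c["mass"]), reverse=True)
    return ClusterResult(clusters, n_perm, thr, df)
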