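"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the DBSCAN
oracle works from the dense pairwise-distance matrix and graph
connectivity, and the AUC oracle counts (positive, negative) pairs
explicitly.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def dbscan_labels_oracle(mz: np.ndarray, eps: float, min_density: int) -> np.ndarray:
    """Density-reachability labels from the dense pairwise distance matrix.

    Cores are points with >= min_density neighbors within eps (self
    included); clusters are connected components of the core-core
    within-eps graph; every non-core point within eps of a core joins the
    cluster of its nearest core (ties to the lower-m/z core). Returns an
    integer label per input point, -1 for noise; labels are canonicalized
    by the minimum member index of each cluster.
    """
    mz = np.asarray(mz, float)
    n = len(mz)
    if n == 0:
        return np.array([], dtype=int)
    close = np.abs(mz[:, None] - mz[None, :]) <= eps
    core = close.sum(axis=1) >= min_density
    labels = np.full(n, -1, dtype=int)
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels
    adj = csr_matrix(close[np.ix_(core_idx, core_idx)])
    _, comp = connected_components(adj, directed=False)
    labels[core_idx] = comp
    noncore_idx = np.flatnonzero(~core)
    if len(noncore_idx):
        dist = np.abs(mz[noncore_idx][:, None] - mz[core_idx][None, :])
        # nearest core; np.argmin ties to the first, i.e. lowest index —
        # order core_idx by m/z (stable) so ties go to the lower-m/z core
        order = np.argsort(mz[core_idx], kind="stable")
        dist = dist[:, order]
        nearest = np.argmin(dist, axis=1)
        reach = dist[np.arange(len(noncore_idx)), nearest] <= eps
        labels[noncore_idx[reach]] = comp[order][nearest[reach]]
    return _canonicalize(labels)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def groups_to_labels(groups, n: int) -> np.ndarray:
    """Convert PeakGroup membership into canonical per-point labels."""
    labels = np.full(n, -1, dtype=int)
    for g in sorted(groups, key=lambda g: int(np.min(g.member_idx))):
        labels[g.member_idx] = max(labels.max(), -1) + 1
    return _canonicalize(labels)


def auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by explicit pair counting: wins plus half-ties over all pairs."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins) / (pos.size * neg.size)
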