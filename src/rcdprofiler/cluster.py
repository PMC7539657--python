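"""Ward hierarchical clustering and cluster-number selection.

The linkage is computed by the Lance–Williams recurrence on squared
heights,

    d²(k, i∪j) = [(n_i+n_k) d²(i,k) + (n_j+n_k) d²(j,k) − n_k d²(i,j)]
                 / (n_i + n_j + n_k),

which for Euclidean input distances is exactly Ward's variance-minimizing
criterion: the height of a merge equals sqrt(2·ΔESS), the square root of
twice the increase in within-cluster sum of squares.  Tie-breaking is
fully deterministic — among candidate pairs whose merge cost is within a
small tolerance of the minimum, the lexicographically smallest (i, j) pair
of cluster ids is merged — so runs are reproducible bit-for-bit.

The number of flat clusters is chosen by a majority vote of three indices
(Calinski–Harabasz, mean silhouette, within-cluster sum-of-squares elbow),
a deterministic desk-scale replacement for a full multi-index vote; the
per-index table is returned so disagreement can be inspected.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .model import LinkageTree, Merge, PresenceMatrix, RcdError

# cost comparisons closer than this are treated as ties and broken
# lexicographically, keeping merge order stable across algebraically
# equivalent cost computations
_TIE_TOL = 1e-9


def ward_linkage(dist: np.ndarray) -> LinkageTree:
    """Agglomerative Ward linkage from a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise RcdError("distance matrix must be square")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise RcdError("distance matrix must be symmetric with zero diagonal")
    n = dist.shape[0]
    if n < 2:
        raise RcdError("need at least two observations")

    total = 2 * n - 1
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = dist**2
    np.fill_diagonal(d2, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = set(range(n))
    merges: list[Merge] = []

    for step in range(n - 1):
        ids = sorted(active)
        best: Optional[tuple[int, int]] = None
        best_cost = np.inf
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                c = d2[i, j]
                if c < best_cost - _TIE_TOL:
                    best_cost, best = c, (i, j)
                # within tolerance: keep earlier (lexicographically
                # smaller) pair, i.e. do nothing
        assert best is not None
        i, j = best
        k = n + step
        ni, nj = sizes[i], sizes[j]
        height = float(np.sqrt(max(d2[i, j], 0.0)))
        for h in active:
            if h in (i, j):
                continue
            nh = sizes[h]
            d2[k, h] = d2[h, k] = (
                (ni + nh) * d2[i, h] + (nj + nh) * d2[j, h] - nh * d2[i, j]
            ) / (ni + nj + nh)
        sizes[k] = ni + nj
        active -= {i, j}
        active.add(k)
        merges.append(Merge(i, j, height, int(sizes[k])))
    return LinkageTree(merges=merges, n_leaves=n)


# ---------------------------------------------------------------------------
# cluster-number selection

@dataclass
class KSelection:
    k_best: int
    table: pd.DataFrame          # per-k index values and per-index votes
    labels: dict[int, np.ndarray]  # flat labels for each candidate k


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def select_k(
    tree: LinkageTree,
    matrix: PresenceMatrix | np.ndarray,
    k_range: Optional[Sequence[int]] = None,
) -> KSelection:
    """Choose the flat cluster number by 3-index majority vote.

    Candidate k default to 2..min(8, n-1).  Each index nominates its best
    k (Calinski–Harabasz and silhouette by maximum; elbow by maximum
    second difference of the within-cluster sum of squares); the majority
    wins, ties going to the smallest k.  All-identical profiles degenerate
    to k_best = 1 with a warning.
    """
    X = matrix.values().astype(float) if isinstance(matrix, PresenceMatrix) \
        else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise RcdError("cluster-number selection needs at least 3 species")
    if np.all(X == X[0]):
        warnings.warn("all profiles identical; k_best = 1")
        return KSelection(
            k_best=1,
            table=pd.DataFrame(),
            labels={1: np.ones(n, dtype=int)},
        )
    ks = list(k_range) if k_range is not None else list(range(2, min(8, n - 1) + 1))
    if not ks or min(ks) < 2 or max(ks) > n:
        raise RcdError(f"invalid k range {ks} for n={n}")

    labels = {k: tree.cut(k) for k in ks}
    # WSS on a grid extended by one step each side for second differences
    wss_ks = sorted({1, *ks, min(max(ks) + 1, n)})
    wss = {k: _wss(X, tree.cut(k)) for k in wss_ks}

    rows = []
    for k in ks:
        lab = labels[k]
        ch = calinski_harabasz_score(X, lab) if len(np.unique(lab)) > 1 else np.nan
        sil = (
            silhouette_score(X, lab, metric="euclidean")
            if 2 <= len(np.unique(lab)) <= n - 1
            else np.nan
        )
        lo = wss.get(k - 1, wss[1] if k - 1 < 1 else np.nan)
        hi = wss.get(k + 1, np.nan)
        elbow = (
            (lo - wss[k]) - (wss[k] - hi)
            if np.isfinite(lo) and np.isfinite(hi)
            else -np.inf
        )
        rows.append({"k": k, "calinski_harabasz": ch,
                     "silhouette": sil, "wss": wss[k], "elbow_score": elbow})
    table = pd.DataFrame(rows).set_index("k")

    def argbest(col: str) -> int:
        s = table[col]
        if s.isna().all() or not np.isfinite(s.max()):
            return min(ks)
        best = s.max()
        return int(min(k for k in ks if np.isclose(s.loc[k], best) or s.loc[k] >= best))

    votes = {
        "calinski_harabasz": argbest("calinski_harabasz"),
        "silhouette": argbest("silhouette"),
        "elbow_score": argbest("elbow_score"),
    }
    table["vote"] = [
        ",".join(idx for idx, kk in votes.items() if kk == k) for k in table.index
    ]
    counts = Counter(votes.values())
    top = max(counts.values())
    k_best = min(k for k, c in counts.items() if c == top)
    return KSelection(k_best=k_best, table=table, labels=labels)
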