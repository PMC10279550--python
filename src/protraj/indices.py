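"""Cluster-validity index ensemble and the k vote.

Seven indices spanning the compactness/separation families are computed
for every candidate k and each index casts one vote for its optimizing
k; the ensemble winner is the modal vote (ties toward smaller k).  This
mirrors consensus cluster-count selection with an ensemble of validity
measures:

* silhouette (maximize)              — sklearn-backed
* Calinski-Harabasz (maximize)       — sklearn-backed
* Davies-Bouldin (minimize)          — sklearn-backed
* Dunn (maximize)                    — min inter-cluster single-linkage
                                       distance / max cluster diameter
* C-index (minimize)                 — (S_w - S_min) / (S_max - S_min)
* gap statistic, B reference draws from the uniform bounding box and the
  one-standard-error rule (smallest k with gap(k) >= gap(k+1) - s(k+1))
* Hartigan, smallest k with H(k) = (W_k / W_{k+1} - 1)(n - k - 1) <= 10

Indices undefined on a degenerate partition (singleton-dependent
denominators, all-identical points) report ``nan`` for that k and are
excluded from their own vote.  Hartigan and the gap rule need W at
``max(k_range) + 1``, so solutions one k beyond the range are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from .kmeans import kmeans

__all__ = ["INDEX_NAMES", "compute_indices", "vote", "KVoteTable", "score_k_range"]

INDEX_NAMES = ["silhouette", "calinski_harabasz", "davies_bouldin", "dunn",
               "c_index", "gap", "hartigan"]
# optimization direction of the plain value-indices
_MAXIMIZE = {"silhouette": True, "calinski_harabasz": True, "davies_bouldin": False,
             "dunn": True, "c_index": False}


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for j in np.unique(labels):
        pts = X[labels == j]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def silhouette_index(X: np.ndarray, labels: np.ndarray,
                     D: np.ndarray | None = None) -> float:
    """Mean silhouette; difference-based distances for full precision.

    Singleton clusters contribute 0; all points identical gives 0 by
    convention.
    """
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    if np.ptp(X, axis=0).max() == 0:
        return 0.0  # all points identical: defined as 0 by convention
    if D is None:
        D = squareform(pdist(np.asarray(X, float)))
    n = len(labels)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    svals = np.zeros(n)
    mean_d = {c: D[:, masks[c]].sum(axis=1) for c in uniq}  # row sums per cluster
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # silhouette of a singleton is 0
        a = mean_d[c][i] / (sizes[c] - 1)
        b = min(mean_d[o][i] / sizes[o] for o in uniq if o != c)
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(svals.mean())


def ch_index(X: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2 or _within_ss(X, labels) <= 0:
        return np.nan
    return float(calinski_harabasz_score(X, labels))


def db_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin: mean over clusters of the worst (s_i + s_j) / d_ij."""
    X = np.asarray(X, float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    centers = np.array([X[labels == j].mean(axis=0) for j in uniq])
    if np.ptp(centers, axis=0).max() == 0:
        return np.nan  # coincident centroids: 0/0 ratios
    spread = np.array([
        np.linalg.norm(X[labels == j] - centers[i], axis=1).mean()
        for i, j in enumerate(uniq)
    ])
    k = len(uniq)
    total = 0.0
    for i in range(k):
        d = np.linalg.norm(centers - centers[i], axis=1)
        ratios = [(spread[i] + spread[j]) / d[j] for j in range(k)
                  if j != i and d[j] > 0]
        total += max(ratios)
    return total / k


def dunn_index(X: np.ndarray, labels: np.ndarray, D: np.ndarray | None = None) -> float:
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    if D is None:
        D = squareform(pdist(X))
    max_diam = 0.0
    for j in uniq:
        idx = np.flatnonzero(labels == j)
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    if max_diam == 0:
        return np.nan
    min_between = np.inf
    for a in range(len(uniq)):
        ia = np.flatnonzero(labels == uniq[a])
        for b in range(a + 1, len(uniq)):
            ib = np.flatnonzero(labels == uniq[b])
            min_between = min(min_between, float(D[np.ix_(ia, ib)].min()))
    return min_between / max_diam


def c_index_value(X: np.ndarray, labels: np.ndarray, D: np.ndarray | None = None) -> float:
    if D is None:
        D = squareform(pdist(X))
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    n_w = int(same.sum())
    if n_w == 0 or n_w == len(d):
        return np.nan
    s_w = float(d[same].sum())
    ds = np.sort(d)
    s_min = float(ds[:n_w].sum())
    s_max = float(ds[-n_w:].sum())
    if s_max - s_min <= 0:
        return np.nan
    return (s_w - s_min) / (s_max - s_min)


def gap_curve(X: np.ndarray, w_by_k: dict[int, float], k_values: list[int],
              b_ref: int, seed: int, n_init: int = 2):
    """Gap(k) and its 1-SE half-width for every k, sharing one reference set.

    References are drawn uniformly over the per-feature bounding box of
    the data and clustered with the same k-means; the returned ``s``
    includes the sqrt(1 + 1/B) factor of the one-standard-error rule.
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    gaps, ses = {}, {}
    ref_logw = np.empty((b_ref, len(k_values)))
    for b in range(b_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        for jk, k in enumerate(k_values):
            _, _, inertia = kmeans(ref, k, seed=int(rng.integers(2**31)), n_init=n_init)
            ref_logw[b, jk] = np.log(max(inertia, 1e-300))
    for jk, k in enumerate(k_values):
        logw = np.log(max(w_by_k[k], 1e-300))
        gaps[k] = float(ref_logw[:, jk].mean() - logw)
        sd = float(ref_logw[:, jk].std(ddof=0))
        ses[k] = sd * np.sqrt(1.0 + 1.0 / b_ref)
    return gaps, ses


def gap_vote(gaps: dict[int, float], ses: dict[int, float], k_range: list[int]) -> int:
    for k in k_range:
        if k + 1 in gaps and gaps[k] >= gaps[k + 1] - ses[k + 1]:
            return k
    return max(k_range, key=lambda k: gaps[k])


def hartigan_values(w_by_k: dict[int, float], n: int, k_range: list[int]) -> dict[int, float]:
    out = {}
    for k in k_range:
        if k + 1 not in w_by_k or w_by_k[k + 1] <= 0:
            out[k] = np.nan
        else:
            out[k] = (w_by_k[k] / w_by_k[k + 1] - 1.0) * (n - k - 1)
    return out


def hartigan_vote(h: dict[int, float], threshold: float = 10.0) -> int | None:
    ks = sorted(k for k, v in h.items() if np.isfinite(v))
    if not ks:
        return None
    for k in ks:
        if h[k] <= threshold:
            return k
    return min(ks, key=lambda k: h[k])  # no k crosses the threshold


@dataclass
class KVoteTable:
    values: pd.DataFrame          # index k, columns INDEX_NAMES (gap/hartigan raw values)
    votes: dict[str, int]         # index name -> its chosen k (missing if undefined)
    winner: int


def compute_indices(X: np.ndarray, labels_by_k: dict[int, np.ndarray],
                    k_range: list[int]) -> pd.DataFrame:
    D = squareform(pdist(X))
    rows = {}
    for k in k_range:
        lab = labels_by_k[k]
        rows[k] = {
            "silhouette": silhouette_index(X, lab, D),
            "calinski_harabasz": ch_index(X, lab),
            "davies_bouldin": db_index(X, lab),
            "dunn": dunn_index(X, lab, D),
            "c_index": c_index_value(X, lab, D),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def vote(votes: dict[str, int], k_range: list[int]) -> int:
    """Modal vote over indices; ties broken toward smaller k."""
    cast = [k for k in votes.values() if k is not None]
    if not cast:
        raise ValueError("every validity index was undefined; cannot vote")
    counts = {k: 0 for k in sorted(set(cast))}
    for k in cast:
        counts[k] += 1
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)


def score_k_range(X: np.ndarray, k_range: tuple[int, int], seed: int,
                  n_init: int = 25, gap_b: int = 20) -> KVoteTable:
    """Cluster X for each k in the inclusive range, compute the ensemble, vote.

    Solutions at ``k_max + 1`` are computed as well because the Hartigan
    and gap rules compare successive k.
    """
    ks = list(range(k_range[0], k_range[1] + 1))
    ks_ext = ks + [ks[-1] + 1]
    rng = np.random.default_rng(seed)
    labels_by_k, w_by_k = {}, {}
    for k in ks_ext:
        if k > len(X):
            break
        lab, _, inertia = kmeans(X, k, seed=int(rng.integers(2**31)), n_init=n_init)
        labels_by_k[k] = lab
        w_by_k[k] = inertia
    ks = [k for k in ks if k in labels_by_k]
    table = compute_indices(X, labels_by_k, ks)

    votes: dict[str, int] = {}
    for name, maximize in _MAXIMIZE.items():
        col = table[name]
        if col.notna().any():
            votes[name] = int(col.idxmax() if maximize else col.idxmin())
    gaps, ses = gap_curve(X, w_by_k, list(labels_by_k), gap_b, int(rng.integers(2**31)))
    table["gap"] = [gaps[k] for k in ks]
    votes["gap"] = gap_vote(gaps, ses, ks)
    h = hartigan_values(w_by_k, len(X), ks)
    table["hartigan"] = [h[k] for k in ks]
    hv = hartigan_vote(h)
    if hv is not None:
        votes["hartigan"] = hv
    winner = vote(votes, ks)
    table.index.name = "k"
    return KVoteTable(table, votes, winner)
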