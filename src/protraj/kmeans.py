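"""Lloyd k-means with k-means++ seeding.

A self-contained implementation is used so the within-cluster
sum-of-squares objective can be asserted non-increasing across Lloyd
iterations (a guard on the whole consensus machinery built on top), and
so every clustering call in the bootstrap/stability loops is a pure
function of its seed.  All ``n_init`` restarts run in lockstep on 3-D
arrays, which keeps the many small clustering problems of the bootstrap
loops cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kmeans"]


def _plus_plus_init(X: np.ndarray, k: int, n_init: int,
                    rng: np.random.Generator) -> np.ndarray:
    """k-means++ centers for every restart; returns (n_init, k, d)."""
    n = X.shape[0]
    centers = np.empty((n_init, k, X.shape[1]))
    for i in range(n_init):
        centers[i, 0] = X[rng.integers(n)]
        d2 = ((X - centers[i, 0]) ** 2).sum(axis=1)
        for j in range(1, k):
            total = d2.sum()
            if total <= 0:
                centers[i, j] = X[rng.integers(n)]
                continue
            centers[i, j] = X[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, ((X - centers[i, j]) ** 2).sum(axis=1))
    return centers


def kmeans(X, k: int, seed: int, n_init: int = 25, max_iter: int = 300):
    """Best-of-``n_init`` k-means++ runs; returns (labels, centers, inertia)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")
    rng = np.random.default_rng(seed)
    if k == n:
        return np.arange(n), X.copy(), 0.0

    centers = _plus_plus_init(X, k, n_init, rng)          # (I, k, d)
    x2 = (X**2).sum(axis=1)                               # (n,)
    prev_inertia = np.full(n_init, np.inf)
    offsets = (np.arange(n_init) * k)[:, None]
    xrep = np.broadcast_to(X.T[:, None, :], (d, n_init, n))

    def _assign(cen):
        # d2[i, p, j] = ||x_p - c_ij||^2 for all restarts via one gemm
        prod = (X @ cen.reshape(n_init * k, d).T).reshape(n, n_init, k)
        d2 = (x2[:, None, None] - 2.0 * prod
              + (cen**2).sum(axis=2)[None, :, :])
        lab = d2.argmin(axis=2).T                     # (I, n)
        pd2 = np.maximum(d2.min(axis=2).T, 0.0)       # (I, n)
        return lab, pd2

    for _ in range(max_iter):
        labels, point_d2 = _assign(centers)
        inertia = point_d2.sum(axis=1)
        # Lloyd's objective is non-increasing per restart; a rise is a bug
        assert np.all(inertia <= prev_inertia + 1e-8 * np.maximum(1.0, np.abs(prev_inertia))), \
            "k-means objective increased across Lloyd iterations"
        converged = np.all(prev_inertia - inertia <= 1e-12)
        prev_inertia = inertia
        if converged:
            break
        flat = (labels + offsets).ravel()
        counts = np.bincount(flat, minlength=n_init * k).reshape(n_init, k)
        new_centers = np.empty_like(centers)
        for dim in range(d):
            sums = np.bincount(flat, weights=xrep[dim].ravel(),
                               minlength=n_init * k).reshape(n_init, k)
            new_centers[:, :, dim] = sums / np.maximum(counts, 1)
        empty_i, empty_j = np.nonzero(counts == 0)
        for i, j in zip(empty_i, empty_j):  # re-seed at the worst-fitted point
            new_centers[i, j] = X[int(point_d2[i].argmax())]
        centers = new_centers

    labels, point_d2 = _assign(centers)
    inertia = point_d2.sum(axis=1)
    best = int(inertia.argmin())
    return labels[best], centers[best], float(inertia[best])
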