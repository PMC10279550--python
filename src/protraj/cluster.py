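"""Patient clustering: embedding, consensus k-selection, assignment, stability.

The feature matrix is reduced to a low-dimensional embedding (UMAP by
default; PCA and identity are exact, deterministic alternatives), the
number of clusters is chosen by running the seven-index validity vote on
bootstrap-resampled datasets (each resample is re-embedded, mirroring
the way consensus selection is applied to resampled data), patients are
assigned by k-means at the final k, and the allocation's stability is
quantified by re-clustering noise-perturbed copies of the features and
recording, per original cluster, the best Jaccard match among the
perturbed clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .indices import score_k_range
from .kmeans import kmeans

__all__ = [
    "EmbeddingConfig",
    "embed",
    "ClusterSolution",
    "kmeans_assign",
    "KSelectionResult",
    "select_k_bootstrap",
    "jaccard",
    "StabilityReport",
    "stability",
    "ConsensusClusterer",
]


@dataclass
class EmbeddingConfig:
    method: str = "umap"          # umap | pca | none
    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("umap", "pca", "none"):
            raise ValueError(f"unknown embedding method {self.method!r}")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


def embed(features, config: EmbeddingConfig) -> np.ndarray:
    """Reduce features to ``n_components`` dimensions; seeded and deterministic."""
    X = np.asarray(features, dtype=float)
    if config.method == "none":
        return X
    if X.shape[0] < config.n_components + 1:
        raise ValueError("need at least n_components + 1 samples to embed")
    if config.method == "pca":
        pca = PCA(n_components=config.n_components, svd_solver="full",
                  random_state=config.seed)
        return pca.fit_transform(X)
    if config.n_neighbors >= X.shape[0]:
        raise ValueError("n_neighbors must be smaller than the number of samples")
    import umap  # deferred: numba compilation is costly at import time

    reducer = umap.UMAP(
        n_components=config.n_components,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        random_state=config.seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


@dataclass
class ClusterSolution:
    labels: pd.Series             # patient_id -> 1..k, canonicalized
    centroids: np.ndarray         # (k, d) in embedding space, canonical order
    k: int
    inertia: float                # within-cluster sum of squares
    seed: int
    n_init: int

    def members(self, cluster: int) -> set:
        return set(self.labels.index[self.labels == cluster])


def _canonicalize(raw_labels: np.ndarray, centers: np.ndarray,
                  index) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 1..k by decreasing size; ties by smallest member id."""
    ids = np.asarray(index)
    uniq = np.unique(raw_labels)
    order = sorted(
        uniq,
        key=lambda j: (-int((raw_labels == j).sum()), min(ids[raw_labels == j])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([remap[j] for j in raw_labels])
    new_centers = centers[[int(np.flatnonzero(uniq == old)[0]) for old in order]]
    return new_labels, new_centers


def kmeans_assign(embedding, k: int, seed: int, n_init: int = 25,
                  index=None) -> ClusterSolution:
    """Best-of-``n_init`` k-means at fixed k with canonical cluster numbering."""
    X = np.asarray(embedding, dtype=float)
    if index is None:
        index = pd.RangeIndex(len(X))
    labels, centers, inertia = kmeans(X, k, seed=seed, n_init=n_init)
    lab, cen = _canonicalize(labels, centers, index)
    return ClusterSolution(pd.Series(lab, index=index, name="cluster"),
                           cen, k, inertia, seed, n_init)


@dataclass
class KSelectionResult:
    k_range: tuple[int, int]
    winners: list[int]            # winning k per resample
    histogram: dict[int, int]     # vote histogram over k_range
    modal_k: int
    full_data_table: pd.DataFrame  # per-index per-k values on the full data
    skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.histogram)
        return pd.DataFrame({"k": ks, "votes": [self.histogram[k] for k in ks]})


def select_k_bootstrap(features, embed_config: EmbeddingConfig,
                       k_range: tuple[int, int] = (2, 8), B: int = 100,
                       seed: int = 0, n_init: int = 25,
                       gap_b: int = 20) -> KSelectionResult:
    """Ensemble-vote the cluster count on B bootstrap resamples.

    Each resample draws patients with replacement (duplicates kept),
    re-embeds, clusters every candidate k and records the seven-index
    vote; the modal winning k across resamples is reported together with
    the vote table of the full data.
    """
    X = np.asarray(features, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 patients for bootstrap k-selection")
    rng = np.random.default_rng(seed)
    winners: list[int] = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(X.shape[0], size=X.shape[0])
        sub = X[idx]
        cfg = EmbeddingConfig(**{**asdict(embed_config),
                                 "seed": int(rng.integers(2**31))})
        try:
            emb = embed(sub, cfg)
            res = score_k_range(emb, k_range, seed=int(rng.integers(2**31)),
                                n_init=n_init, gap_b=gap_b)
            winners.append(res.winner)
        except ValueError:
            skipped += 1
    if not winners:
        raise ValueError("every bootstrap resample failed")
    hist = {k: 0 for k in range(k_range[0], k_range[1] + 1)}
    for k in winners:
        hist[k] += 1
    best = max(hist.values())
    modal = min(k for k, c in hist.items() if c == best)
    full = score_k_range(embed(X, embed_config), k_range,
                         seed=int(rng.integers(2**31)), n_init=n_init, gap_b=gap_b)
    return KSelectionResult(k_range, winners, hist, modal, full.values, skipped)


def jaccard(a, b) -> float:
    """|A n B| / |A u B|; two empty sets are identical, hence 1."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class StabilityReport:
    mean_jaccard: dict[int, float]   # original cluster -> mean best Jaccard
    tau: float
    repeats: int
    stable: dict[int, bool] = field(default_factory=dict)
    threshold: float = 0.75

    def __post_init__(self) -> None:
        if not self.stable:
            self.stable = {c: v >= self.threshold for c, v in self.mean_jaccard.items()}

    def to_frame(self) -> pd.DataFrame:
        cs = sorted(self.mean_jaccard)
        return pd.DataFrame({
            "cluster": cs,
            "mean_jaccard": [self.mean_jaccard[c] for c in cs],
            "stable": [self.stable[c] for c in cs],
        })


def stability(features, solution: ClusterSolution, embed_config: EmbeddingConfig,
              tau: float = 0.1, repeats: int = 100, seed: int = 0,
              fresh_seeds: bool = True) -> StabilityReport:
    """Jaccard stability of a cluster allocation under feature-space noise.

    Each repeat adds i.i.d. N(0, tau^2) noise to the standardized
    feature matrix, re-runs the embedding and k-means at the same k, and
    records for every original cluster the maximum Jaccard similarity
    against any perturbed cluster (a label-free match).  With
    ``fresh_seeds=False`` the original embedding/clustering seeds are
    reused, so tau = 0 reproduces the original allocation exactly.
    """
    if tau < 0:
        raise ValueError("noise SD tau must be nonnegative")
    X = np.asarray(features, dtype=float)
    index = solution.labels.index
    rng = np.random.default_rng(seed)
    sums = {c: 0.0 for c in sorted(solution.labels.unique())}
    orig_members = {c: solution.members(c) for c in sums}
    for _ in range(repeats):
        noisy = X + rng.normal(0.0, tau, size=X.shape) if tau > 0 else X.copy()
        if fresh_seeds:
            e_seed, k_seed = int(rng.integers(2**31)), int(rng.integers(2**31))
        else:
            e_seed, k_seed = embed_config.seed, solution.seed
        cfg = EmbeddingConfig(**{**asdict(embed_config), "seed": e_seed})
        emb = embed(noisy, cfg)
        pert = kmeans_assign(emb, solution.k, seed=k_seed, n_init=solution.n_init,
                             index=index)
        pert_members = [pert.members(c) for c in sorted(pert.labels.unique())]
        for c, mem in orig_members.items():
            sums[c] += max(jaccard(mem, pm) for pm in pert_members)
    means = {c: s / repeats for c, s in sums.items()}
    return StabilityReport(means, tau, repeats)


class ConsensusClusterer(BaseEstimator, ClusterMixin):
    """Embed, vote the cluster count on bootstrap resamples, assign by k-means.

    Parameters mirror the pipeline configuration: ``final_k=None`` takes
    the modal bootstrap k.  After ``fit``: ``k_selection_``,
    ``solution_``, ``labels_`` (canonical 1..k), ``embedding_``.
    """

    def __init__(self, method: str = "umap", n_components: int = 2,
                 n_neighbors: int = 15, min_dist: float = 0.1,
                 k_range: tuple[int, int] = (2, 8), B: int = 100,
                 final_k: int | None = None, n_init: int = 25,
                 gap_b: int = 20, seed: int = 0):
        self.method = method
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.k_range = k_range
        self.B = B
        self.final_k = final_k
        self.n_init = n_init
        self.gap_b = gap_b
        self.seed = seed

    def _embed_config(self, seed: int) -> EmbeddingConfig:
        return EmbeddingConfig(self.method, self.n_components, self.n_neighbors,
                               self.min_dist, seed)

    def fit(self, X, y=None):
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        rng = np.random.default_rng(self.seed)
        sel_seed, emb_seed, km_seed = (int(rng.integers(2**31)) for _ in range(3))
        self.k_selection_ = select_k_bootstrap(
            X, self._embed_config(emb_seed), k_range=tuple(self.k_range), B=self.B,
            seed=sel_seed, n_init=self.n_init, gap_b=self.gap_b)
        k = self.final_k or self.k_selection_.modal_k
        self.embed_config_ = self._embed_config(emb_seed)
        self.embedding_ = embed(np.asarray(X, float), self.embed_config_)
        self.solution_ = kmeans_assign(self.embedding_, k, seed=km_seed,
                                       n_init=self.n_init, index=index)
        self.labels_ = self.solution_.labels.to_numpy()
        return self

    def stability_report(self, X, tau: float = 0.1, repeats: int = 100,
                         seed: int | None = None,
                         fresh_seeds: bool = True) -> StabilityReport:
        if seed is None:
            seed = self.seed + 1
        return stability(X, self.solution_, self.embed_config_, tau=tau,
                         repeats=repeats, seed=seed, fresh_seeds=fresh_seeds)
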