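"""Protein subsets and subphenotype driver statistics.

Proteins (not patients) are clustered into subsets with k-means on the
transposed feature block — intercepts and slopes separately — with the
cluster count chosen by the same seven-index vote in a single pass.
Each protein's association with the patient subphenotypes is quantified
by a Kruskal-Wallis test on its per-patient feature values, corrected
across all proteins of the axis by Benjamini-Hochberg; the fraction of
significant proteins per subset identifies which subsets drive the
allocation.  Per-patient subset scores are the shrunken patient means of
a random-intercepts model over the subset's proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .indices import score_k_range
from .kmeans import kmeans
from .lme import fit_random_intercept

__all__ = [
    "ProteinSubsetPartition",
    "cluster_proteins",
    "kruskal_wallis",
    "bh_adjust",
    "DriverStats",
    "driver_summary",
    "subset_patient_score",
]


@dataclass
class ProteinSubsetPartition:
    axis: str                      # "intercept" | "slope"
    labels: pd.Series              # protein -> subset letter
    k: int
    sizes: dict[str, int]
    vote_table: pd.DataFrame


def _letters(n: int) -> list[str]:
    out = []
    for i in range(n):
        name = ""
        j = i
        while True:
            name = ascii_uppercase[j % 26] + name
            j = j // 26 - 1
            if j < 0:
                break
        out.append(name)
    return out


def cluster_proteins(features: pd.DataFrame, axis: str,
                     k_range: tuple[int, int] = (2, 8), seed: int = 0,
                     n_init: int = 25, gap_b: int = 20) -> ProteinSubsetPartition:
    """Cluster the proteins of one axis block; subsets lettered by size.

    ``features`` is the standardized (patients x (feature, protein))
    matrix; the selected axis block is transposed so proteins are the
    objects and patients the dimensions.  k is the single-pass ensemble
    vote; subsets are canonicalized by decreasing size (ties by smallest
    protein id) and lettered A, B, C, ...
    """
    if axis not in ("intercept", "slope"):
        raise ValueError(f"axis must be 'intercept' or 'slope', got {axis!r}")
    block = features[axis] if isinstance(features.columns, pd.MultiIndex) else features
    Xp = block.to_numpy(float).T          # proteins x patients
    proteins = np.asarray(block.columns)
    if len(proteins) < k_range[0]:
        raise ValueError("fewer proteins than the smallest candidate k")
    rng = np.random.default_rng(seed)
    res = score_k_range(Xp, k_range, seed=int(rng.integers(2**31)),
                        n_init=n_init, gap_b=gap_b)
    k = res.winner
    raw, _, _ = kmeans(Xp, k, seed=int(rng.integers(2**31)), n_init=n_init)
    order = sorted(np.unique(raw),
                   key=lambda j: (-int((raw == j).sum()), min(proteins[raw == j])))
    letters = _letters(len(order))
    remap = {old: letters[i] for i, old in enumerate(order)}
    labels = pd.Series([remap[j] for j in raw], index=proteins, name="subset")
    sizes = {letter: int((labels == letter).sum()) for letter in letters}
    return ProteinSubsetPartition(axis, labels, k, sizes, res.values)


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square df = groups - 1."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if np.ptp(values) == 0:
        return 0.0, len(uniq) - 1, 1.0  # identical observations
    h, p = stats.kruskal(*samples)
    return float(h), len(uniq) - 1, float(p)


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags."""
    p = np.asarray(pvalues, float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class DriverStats:
    axis: str
    per_protein: pd.DataFrame     # protein, subset, H, df, p, q, significant
    per_subset: pd.DataFrame      # subset, n, n_significant, fraction_significant
    top_drivers: dict[str, pd.DataFrame] = field(default_factory=dict)


def driver_summary(partition: ProteinSubsetPartition, axis_values: pd.DataFrame,
                   patient_labels: pd.Series, alpha: float = 0.05,
                   top_n: int = 10) -> DriverStats:
    """Kruskal-Wallis per protein vs the subphenotypes, BH across the axis.

    ``axis_values`` holds the per-patient feature values of the
    partition's axis (patients x proteins); ``patient_labels`` the
    subphenotype allocation.  Top drivers per subset are ranked by
    ascending q then descending H.
    """
    labels = patient_labels.loc[axis_values.index].to_numpy()
    rows = []
    for protein in partition.labels.index:
        h, df, p = kruskal_wallis(axis_values[protein].to_numpy(), labels)
        rows.append((protein, partition.labels[protein], h, df, p))
    per = pd.DataFrame(rows, columns=["protein", "subset", "H", "df", "p"])
    per["q"], per["significant"] = bh_adjust(per["p"].to_numpy(), alpha)
    agg = per.groupby("subset").agg(
        n=("protein", "size"), n_significant=("significant", "sum"))
    agg["fraction_significant"] = agg["n_significant"] / agg["n"]
    top = {
        s: grp.sort_values(["q", "H"], ascending=[True, False]).head(top_n)
        for s, grp in per.groupby("subset")
    }
    return DriverStats(partition.axis, per, agg.reset_index(), top)


def subset_patient_score(axis_values: pd.DataFrame, subset_proteins,
                         patients=None) -> tuple[pd.Series, bool]:
    """Per-patient score of one protein subset via a random-intercepts model.

    Fits x_ip = mu + u_i + e_ip over the subset's proteins and returns
    score_i = mu + BLUP(u_i) (the shrunken patient mean), plus a flag
    that is True when the between-patient variance collapsed to zero.
    """
    cols = list(subset_proteins)
    if not cols:
        raise ValueError("subset is empty")
    sub = axis_values[cols]
    if patients is not None:
        sub = sub.loc[patients]
    x = sub.to_numpy(float).ravel()                     # row-major: patient-blocks
    codes = np.repeat(np.arange(len(sub)), len(cols))
    fit = fit_random_intercept(x, codes)
    return pd.Series(fit.scores, index=sub.index, name="score"), fit.collapsed
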