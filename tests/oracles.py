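"""Independent brute-force oracles used to verify the pipeline numerics.

Every function here follows the textbook formula directly with explicit
loops and dense linear algebra, deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# cluster-validity indices

def silhouette_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        bs = []
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            bs.append(np.mean([np.linalg.norm(X[i] - X[j]) for j in other]))
        b = min(bs)
        denom = max(a, b)
        svals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(svals))


def ch_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n, k = len(X), len(set(labels))
    grand = X.mean(axis=0)
    B = W = 0.0
    for c in set(labels):
        pts = X[labels == c]
        cen = pts.mean(axis=0)
        B += len(pts) * np.sum((cen - grand) ** 2)
        W += np.sum((pts - cen) ** 2)
    return (B / (k - 1)) / (W / (n - k))


def db_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    cats = sorted(set(labels))
    cens = [X[labels == c].mean(axis=0) for c in cats]
    # mean distance of cluster members to their centroid
    s = [np.mean([np.linalg.norm(x - cens[i]) for x in X[labels == c]])
         for i, c in enumerate(cats)]
    total = 0.0
    for i in range(len(cats)):
        ratios = [
            (s[i] + s[j]) / np.linalg.norm(cens[i] - cens[j])
            for j in range(len(cats)) if j != i
        ]
        total += max(ratios)
    return total / len(cats)


def dunn_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    cats = sorted(set(labels))
    diam = 0.0
    for c in cats:
        pts = X[labels == c]
        for a, b in itertools.combinations(range(len(pts)), 2):
            diam = max(diam, np.linalg.norm(pts[a] - pts[b]))
    between = math.inf
    for ci, cj in itertools.combinations(cats, 2):
        for a in X[labels == ci]:
            for b in X[labels == cj]:
                between = min(between, np.linalg.norm(a - b))
    return between / diam


def c_index_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    dists, within = [], []
    for i, j in itertools.combinations(range(len(X)), 2):
        d = np.linalg.norm(X[i] - X[j])
        dists.append(d)
        if labels[i] == labels[j]:
            within.append(d)
    nw = len(within)
    dists.sort()
    s_w = sum(within)
    s_min = sum(dists[:nw])
    s_max = sum(dists[-nw:])
    return (s_w - s_min) / (s_max - s_min)


def within_ss_brute(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    w = 0.0
    for c in set(labels):
        pts = X[labels == c]
        w += np.sum((pts - pts.mean(axis=0)) ** 2)
    return float(w)


def hartigan_brute(X, labels_k, labels_k1, k):
    wk = within_ss_brute(X, labels_k)
    wk1 = within_ss_brute(X, labels_k1)
    return (wk / wk1 - 1.0) * (len(X) - k - 1)


# ---------------------------------------------------------------------------
# Henderson mixed-model equations (dense)

def henderson_blups(times_by_patient, y_by_patient, G, sigma2=1.0):
    """Solve the dense MME for the random-intercept-slope model with known
    variance components D = sigma2*G; returns (beta, per-patient beta + b_i)."""
    m = len(times_by_patient)
    X = np.vstack([np.column_stack([np.ones(len(t)), t]) for t in times_by_patient])
    y = np.concatenate(y_by_patient)
    N = len(y)
    Z = np.zeros((N, 2 * m))
    row = 0
    for i, t in enumerate(times_by_patient):
        Z[row:row + len(t), 2 * i] = 1.0
        Z[row:row + len(t), 2 * i + 1] = t
        row += len(t)
    Ginv = np.linalg.inv(G)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + np.kron(np.eye(m), Ginv)])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    beta = sol[:2]
    b = sol[2:].reshape(m, 2)
    return beta, beta[None, :] + b


def random_intercept_scores_closed_form(x_matrix):
    """Balanced one-way shrinkage: mu + psi2/(psi2 + s2/P) * (xbar_i - mu)
    with ANOVA(=REML, balanced) variance components."""
    x = np.asarray(x_matrix, float)
    n, P = x.shape
    mu = x.mean()
    xbar = x.mean(axis=1)
    msw = np.sum((x - xbar[:, None]) ** 2) / (n * (P - 1))
    msb = P * np.sum((xbar - mu) ** 2) / (n - 1)
    psi2 = max((msb - msw) / P, 0.0)
    lam = psi2 / (psi2 + msw / P) if psi2 > 0 else 0.0
    return mu + lam * (xbar - mu)


# ---------------------------------------------------------------------------
# survival

def harrell_c_brute(scores, times, events):
    s = np.asarray(scores, float)
    T = np.asarray(times, float)
    E = np.asarray(events, bool)
    num = den = 0.0
    for i in range(len(T)):
        for j in range(len(T)):
            if T[i] < T[j] and E[i]:
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


def cox_grid_beta(z, times, events, lo=-3.0, hi=3.0, tol=1e-6):
    """1-D Breslow/Efron-free (no ties) partial-likelihood grid maximizer."""
    z = np.asarray(z, float)
    T = np.asarray(times, float)
    E = np.asarray(events, bool)

    def ll(beta):
        out = 0.0
        for i in range(len(T)):
            if not E[i]:
                continue
            risk = T >= T[i]
            out += beta * z[i] - np.log(np.sum(np.exp(beta * z[risk])))
        return out

    while hi - lo > tol:
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if ll(m1) < ll(m2):
            lo = m1
        else:
            hi = m2
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# rank tests / multiple testing

def kruskal_h_brute(values, groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum definition."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = len(values)
    order = np.argsort(values)
    ranks = np.empty(n)
    i = 0
    sv = values[order]
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    for g in set(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / corr


def bh_stepup_brute(p, alpha=0.05):
    """Step-up BH: reject the first i_max hypotheses with p_(i) <= i*alpha/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    imax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            imax = rank
    reject = np.zeros(m, bool)
    reject[order[:imax]] = True
    return reject
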