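"""Linear mixed-effects engine for per-protein trajectory features.

One model is fitted per protein to its standardized longitudinal values:

    y_ij = (b0 + u0_i) + (b1 + u1_i) * t_ij + e_ij,
    (u0_i, u1_i) ~ N(0, D),   e_ij ~ N(0, s2),

with patients i and visit times t_ij in years since baseline.  Variance
components are estimated by profiled REML: D is parameterized as
``s2 * L L'`` with a log-Cholesky factor L (PSD by construction) and the
residual variance is profiled out in closed form.  Because each patient
contributes only a handful of visits, every per-patient matrix operation
reduces to 2x2 algebra via the Woodbury identity

    (I + X_i G X_i')^{-1} = I - X_i G (I + X_i'X_i G)^{-1} X_i',

so a full REML evaluation is a single batched pass over patients.  The
per-patient features are empirical BLUPs: fixed effect plus predicted
random effect, i.e. the shrunken patient-specific intercept and slope.

When the estimated random-slope variance collapses below a floor the
model is refitted as random-intercept-only and flagged; a protein whose
values are constant yields a degenerate flagged fit with constant
features.  A random-intercept-only one-way model (no time trend) is also
exposed for per-patient subset scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

__all__ = ["LMEDesign", "LMEFit", "reml_fit", "fit_lme", "predict_features",
           "fit_random_intercept", "RandomInterceptFit"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMEFit:
    beta: np.ndarray              # (2,) fixed intercept and slope
    beta_se: np.ndarray           # (2,) Wald standard errors of the fixed effects
    D: np.ndarray                 # 2x2 random-effects covariance
    sigma2: float                 # residual variance
    reml_criterion: float         # -2 * restricted log-likelihood at the optimum
    converged: bool
    model_form: str               # "full" | "intercept_only"
    degenerate: bool = False
    n_obs: int = 0
    n_patients: int = 0
    criterion_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def G(self) -> np.ndarray:
        """Scaled covariance D / sigma2 used in the Woodbury algebra."""
        if self.sigma2 <= 0:
            return self.D * np.inf
        return self.D / self.sigma2


class LMEDesign:
    """Per-patient time designs, shared across all proteins of a cohort.

    Rows must be sorted so that each patient's observations are
    contiguous; ``starts`` are the reduceat segment offsets.
    """

    def __init__(self, patient_codes: np.ndarray, times: np.ndarray):
        order = np.argsort(patient_codes, kind="stable")
        self.order = order
        codes = np.asarray(patient_codes)[order]
        t = np.asarray(times, dtype=float)[order]
        change = np.flatnonzero(np.diff(codes)) + 1
        self.starts = np.concatenate([[0], change])
        self.patient_codes = codes[self.starts]
        self.t = t
        self.n_i = np.diff(np.append(self.starts, len(t)))
        ones = np.ones_like(t)
        s1 = np.add.reduceat(ones, self.starts)
        st = np.add.reduceat(t, self.starts)
        stt = np.add.reduceat(t * t, self.starts)
        self.A = np.empty((len(self.starts), 2, 2))
        self.A[:, 0, 0] = s1
        self.A[:, 0, 1] = self.A[:, 1, 0] = st
        self.A[:, 1, 1] = stt
        # scalar components, used by the hot vectorized REML path
        self.a11, self.a12, self.a22 = s1, st, stt
        self.N = len(t)
        self.m = len(self.starts)

    def stats_for(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Per-patient X'y (m,2) and total y'y for one protein."""
        yo = np.asarray(y, dtype=float)[self.order]
        B = np.empty((self.m, 2))
        B[:, 0] = np.add.reduceat(yo, self.starts)
        B[:, 1] = np.add.reduceat(yo * self.t, self.starts)
        return B, float(yo @ yo)


def _theta_to_G(theta: np.ndarray) -> np.ndarray:
    th = np.clip(theta, -13.0, 13.0)
    L = np.array([[np.exp(th[0]), 0.0], [th[1], np.exp(th[2])]])
    return L @ L.T


def _m_components(design: LMEDesign, G: np.ndarray):
    """Per-patient M_i = (G^{-1} + A_i)^{-1} and log|I + A_i G|, written out
    in scalar 2x2 components (the REML hot path; avoids batched matmuls)."""
    a11, a12, a22 = design.a11, design.a12, design.a22
    g11, g12, g22 = G[0, 0], G[0, 1], G[1, 1]
    k11 = 1.0 + a11 * g11 + a12 * g12
    k12 = a11 * g12 + a12 * g22
    k21 = a12 * g11 + a22 * g12
    k22 = 1.0 + a12 * g12 + a22 * g22
    det = k11 * k22 - k12 * k21
    m11 = (g11 * k22 - g12 * k21) / det
    m12 = (g12 * k11 - g11 * k12) / det
    m22 = (g22 * k11 - g12 * k12) / det
    return m11, m12, m22, det


def _gls_pieces(design: LMEDesign, B: np.ndarray, c: float, G: np.ndarray):
    """Summed GLS building blocks at scaled covariance G (Woodbury 2x2 path)."""
    a11, a12, a22 = design.a11, design.a12, design.a22
    m11, m12, m22, det = _m_components(design, G)
    am11 = a11 * m11 + a12 * m12
    am12 = a11 * m12 + a12 * m22
    am21 = a12 * m11 + a22 * m12
    am22 = a12 * m12 + a22 * m22
    S_xx = np.array([
        [np.sum(a11 - (am11 * a11 + am12 * a12)),
         np.sum(a12 - (am11 * a12 + am12 * a22))],
        [0.0,
         np.sum(a22 - (am21 * a12 + am22 * a22))],
    ])
    S_xx[1, 0] = S_xx[0, 1]
    b1, b2 = B[:, 0], B[:, 1]
    S_xy = np.array([np.sum(b1 - (am11 * b1 + am12 * b2)),
                     np.sum(b2 - (am21 * b1 + am22 * b2))])
    S_yy = c - float(np.sum(b1 * (m11 * b1 + m12 * b2) + b2 * (m12 * b1 + m22 * b2)))
    ldet = float(np.log(det).sum())
    return S_xx, S_xy, S_yy, ldet, (m11, m12, m22)


def _crit_from_pieces(S_xx, S_xy, S_yy, ldet, N, p):
    sign, logdet_sxx = np.linalg.slogdet(S_xx)
    if sign <= 0:
        return np.inf, None, None
    beta = np.linalg.solve(S_xx, S_xy)
    rss = max(S_yy - S_xy @ beta, 1e-300)
    df = N - p
    sigma2 = rss / df
    crit = df * (_LOG2PI + np.log(sigma2) + 1.0) + ldet + logdet_sxx
    return crit, beta, sigma2


def _crit_full(theta, design, B, c):
    G = _theta_to_G(theta)
    S_xx, S_xy, S_yy, ldet, _ = _gls_pieces(design, B, c, G)
    return _crit_from_pieces(S_xx, S_xy, S_yy, ldet, design.N, 2)[0]


def _pieces_intercept_only(design: LMEDesign, B: np.ndarray, c: float, g: float):
    u = design.A[:, :, 0]                      # X_i' 1 = (n_i, sum t)
    w = g / (1.0 + g * design.n_i)
    S_xx = design.A.sum(axis=0) - np.einsum("m,mi,mj->ij", w, u, u)
    S_xy = B.sum(axis=0) - np.einsum("m,mi,m->i", w, u, B[:, 0])
    S_yy = c - float(np.sum(w * B[:, 0] ** 2))
    ldet = float(np.log1p(g * design.n_i).sum())
    return S_xx, S_xy, S_yy, ldet, w


def _crit_intercept_only(logg, design, B, c):
    g = float(np.exp(np.clip(logg, -26.0, 26.0)))
    S_xx, S_xy, S_yy, ldet, _ = _pieces_intercept_only(design, B, c, g)
    return _crit_from_pieces(S_xx, S_xy, S_yy, ldet, design.N, 2)[0]


def reml_fit(
    design: LMEDesign,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    slope_var_floor: float = 1e-10,
) -> tuple[LMEFit, np.ndarray]:
    """Fit one protein; returns the fit and the (m,2) BLUP feature matrix."""
    if design.N < 3:
        raise ValueError(f"need at least 3 observations, got {design.N}")
    y = np.asarray(y, dtype=float)
    B, c = design.stats_for(y)
    if np.ptp(y) < 1e-13:
        beta = np.array([float(y[0]), 0.0])
        fit = LMEFit(beta, np.zeros(2), np.zeros((2, 2)), 0.0, -np.inf, True,
                     "intercept_only", degenerate=True, n_obs=design.N,
                     n_patients=design.m)
        return fit, np.tile(beta, (design.m, 1))

    path: list[float] = []

    def crit(theta):
        v = _crit_full(theta, design, B, c)
        path.append(v)
        return v

    x0 = np.array([np.log(0.5), 0.0, np.log(0.5)])
    res = minimize(crit, x0, method="Nelder-Mead",
                   options={"fatol": tol, "xatol": 1e-6, "maxiter": max_iter,
                            "maxfev": 4 * max_iter})
    G = _theta_to_G(res.x)
    S_xx, S_xy, S_yy, ldet, _ = _gls_pieces(design, B, c, G)
    critv, beta, sigma2 = _crit_from_pieces(S_xx, S_xy, S_yy, ldet, design.N, 2)
    D = sigma2 * G

    if D[1, 1] < slope_var_floor:
        return _fit_intercept_only(design, y, B, c, tol, path)

    feats = _blup_features(design, B, beta, G, intercept_only=False)
    best_path = np.minimum.accumulate(np.asarray(path))
    beta_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(S_xx)))
    fit = LMEFit(beta, beta_se, D, float(sigma2), float(critv), bool(res.success),
                 "full", n_obs=design.N, n_patients=design.m,
                 criterion_path=best_path)
    return fit, feats


def _fit_intercept_only(design, y, B, c, tol, path=None):
    res = minimize_scalar(_crit_intercept_only, bounds=(-26.0, 13.0), args=(design, B, c),
                          method="bounded", options={"xatol": 1e-10})
    g = float(np.exp(np.clip(res.x, -26.0, 26.0)))
    S_xx, S_xy, S_yy, ldet, w = _pieces_intercept_only(design, B, c, g)
    critv, beta, sigma2 = _crit_from_pieces(S_xx, S_xy, S_yy, ldet, design.N, 2)
    D = np.array([[sigma2 * g, 0.0], [0.0, 0.0]])
    u = design.A[:, :, 0]
    b0 = w * (B[:, 0] - u @ beta)
    feats = np.column_stack([beta[0] + b0, np.full(design.m, beta[1])])
    hist = np.minimum.accumulate(np.asarray(path)) if path else np.empty(0)
    beta_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(S_xx)))
    fit = LMEFit(beta, beta_se, D, float(sigma2), float(critv), True,
                 "intercept_only", n_obs=design.N, n_patients=design.m,
                 criterion_path=hist)
    return fit, feats


def _blup_features(design, B, beta, G, intercept_only: bool) -> np.ndarray:
    """Empirical BLUPs beta + b_i.

    Uses the push-through identity G X'(I + X G X')^{-1} r =
    (G^{-1} + A)^{-1} X'r, which stays well-conditioned as G grows (the
    noiseless limit where the BLUP approaches the patient's own line).
    """
    a11, a12, a22 = design.a11, design.a12, design.a22
    m11, m12, m22, _ = _m_components(design, G)
    xr1 = B[:, 0] - (a11 * beta[0] + a12 * beta[1])
    xr2 = B[:, 1] - (a12 * beta[0] + a22 * beta[1])
    return np.column_stack([beta[0] + m11 * xr1 + m12 * xr2,
                            beta[1] + m12 * xr1 + m22 * xr2])


def gls_beta_blups(design: LMEDesign, y: np.ndarray, G: np.ndarray):
    """GLS fixed effects and BLUPs at a *fixed* scaled covariance G.

    Used to compare the Woodbury path against dense mixed-model-equation
    solvers; returns (beta, features (m,2)).
    """
    B, c = design.stats_for(y)
    S_xx, S_xy, _, _, _ = _gls_pieces(design, B, c, G)
    beta = np.linalg.solve(S_xx, S_xy)
    return beta, _blup_features(design, B, beta, G, False)


def fit_lme(groups, **kwargs) -> LMEFit:
    """Fit from per-patient ``(times, values)`` series (convenience wrapper)."""
    codes = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    values = np.concatenate([np.asarray(v, float) for _, v in groups])
    if len(times) < 3:
        raise ValueError(f"need at least 3 observations, got {len(times)}")
    if sum(len(t) >= 2 for t, _ in groups) < 2:
        # slope variance unidentifiable without >=2 patients with >=2 points
        design = LMEDesign(codes, times)
        B, c = design.stats_for(values)
        return _fit_intercept_only(design, values, B, c, kwargs.get("tol", 1e-8))[0]
    design = LMEDesign(codes, times)
    fit, _ = reml_fit(design, values, **kwargs)
    return fit


def predict_features(fit: LMEFit, times, values) -> tuple[float, float]:
    """BLUP (intercept, slope) features for one patient's series.

    A patient with no observations gets the population line; under an
    intercept-only model the slope feature is the fixed slope.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.size == 0:
        return float(fit.beta[0]), float(fit.beta[1])
    X = np.column_stack([np.ones_like(t), t])
    if fit.sigma2 <= 0:
        # noiseless limit: the patient's own least-squares line
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if t.size == 1:
            coef = np.array([y[0] - fit.beta[1] * t[0], fit.beta[1]])
        return float(coef[0]), float(coef[1])
    G = fit.D / fit.sigma2
    A = X.T @ X
    K = np.eye(2) + A @ G
    M = G @ np.linalg.inv(K)
    Xr = X.T @ y - A @ fit.beta
    b = M @ Xr
    return float(fit.beta[0] + b[0]), float(fit.beta[1] + b[1])


@dataclass
class RandomInterceptFit:
    mu: float
    psi2: float        # between-patient variance
    sigma2: float      # within-patient variance
    scores: np.ndarray  # mu + BLUP(u_i), one per patient
    collapsed: bool    # psi2 estimated (near) zero: all scores equal mu


def fit_random_intercept(values: np.ndarray, patient_codes: np.ndarray) -> RandomInterceptFit:
    """One-way random-intercept model x_ip = mu + u_i + e_ip by profiled REML.

    Scores are the shrunken patient means mu + BLUP(u_i); when the
    between-patient variance collapses to zero every score equals mu.
    """
    x = np.asarray(values, float)
    codes = np.asarray(patient_codes)
    order = np.argsort(codes, kind="stable")
    x = x[order]
    codes = codes[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1])
    n_i = np.diff(np.append(starts, len(x)))
    s_i = np.add.reduceat(x, starts)
    c = float(x @ x)
    N = len(x)

    def crit(logg):
        g = float(np.exp(np.clip(logg, -30.0, 30.0)))
        w = g / (1.0 + g * n_i)
        S_xx = N - float(np.sum(w * n_i**2))
        S_xy = s_i.sum() - float(np.sum(w * n_i * s_i))
        S_yy = c - float(np.sum(w * s_i**2))
        mu = S_xy / S_xx
        rss = max(S_yy - S_xy * mu, 1e-300)
        sigma2 = rss / (N - 1)
        return (N - 1) * (_LOG2PI + np.log(sigma2) + 1.0) + float(
            np.log1p(g * n_i).sum()) + np.log(S_xx)

    res = minimize_scalar(crit, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-12})
    g = float(np.exp(res.x))
    w = g / (1.0 + g * n_i)
    S_xx = N - float(np.sum(w * n_i**2))
    S_xy = s_i.sum() - float(np.sum(w * n_i * s_i))
    S_yy = c - float(np.sum(w * s_i**2))
    mu = S_xy / S_xx
    sigma2 = max(S_yy - S_xy * mu, 1e-300) / (N - 1)
    psi2 = sigma2 * g
    u = w * (s_i - n_i * mu)
    collapsed = psi2 < 1e-12
    scores = np.full(len(n_i), mu) if collapsed else mu + u
    return RandomInterceptFit(float(mu), float(psi2), float(sigma2), scores, bool(collapsed))
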