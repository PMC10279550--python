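"""Outcome association: clinical comparisons, Cox models, discrimination.

Subphenotypes are compared on clinical covariates (Kruskal-Wallis for
numeric variables; chi-square for categorical unless an expected cell
falls below 5, then Fisher's exact test) and on the hazard of the
composite endpoint via Cox proportional-hazards regressions with four
nested adjustment levels:

1. subphenotype dummies only (reference: cluster 1);
2. plus age, sex and eGFR (forced trio);
3. plus every clinical variable significantly associated with the
   endpoint after BH correction (trio still forced);
4. model 3 plus log NT-proBNP.

The partial likelihood uses Efron tie handling and is maximized by
Newton-Raphson with step-halving.  Discrimination is Harrell's C over
usable pairs, internally validated by Harrell's optimism bootstrap:
refit on each resample, measure the optimism as the drop from
bootstrap-sample C to original-sample C, and subtract the mean optimism
from the apparent C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .subsets import bh_adjust, kruskal_wallis
from .io_formats import ClinicalTable

__all__ = [
    "ConvergenceError",
    "CoxFitResult",
    "fit_cox",
    "harrell_c",
    "optimism_corrected_c",
    "kaplan_meier_logrank",
    "ClinicalComparison",
    "compare_clinical",
    "select_model3_covariates",
    "cox_design",
    "CoxModelSpec",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Efron partial likelihood

def _efron_loglik_grad_hess(beta, X, T, E):
    """Log partial likelihood, gradient and Hessian with Efron tie handling."""
    n, p = X.shape
    order = np.argsort(-T, kind="stable")  # descending time: risk set = prefix
    Xs, Ts, Es = X[order], T[order], E[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and Ts[j + 1] == Ts[i]:
            j += 1
        ev = [r for r in range(i, j + 1) if Es[r]]
        if ev:
            d = len(ev)
            S0 = cw[j]
            S1 = cwx[j]
            S2 = cwxx[j]
            t0 = w[ev].sum()
            t1 = wx[ev].sum(axis=0)
            t2 = wxx[ev].sum(axis=0)
            ll += eta[ev].sum()
            grad += Xs[ev].sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0 - f * t0
                s1 = S1 - f * t1
                s2 = S2 - f * t2
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        i = j + 1
    return ll, grad, hess


@dataclass
class CoxModelSpec:
    """Which of the four nested adjustment levels to fit."""
    level: int = 1
    covariates: list[str] = field(default_factory=list)  # beyond the cluster dummies
    reference_cluster: int = 1
    tie_method: str = "efron"


@dataclass
class CoxFitResult:
    summary: pd.DataFrame        # covariate, coef, se, hr, ci_low, ci_high, p
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int
    apparent_c: float = np.nan
    corrected_c: float = np.nan
    bootstrap_b: int = 0
    n_iter: int = 0
    penalized: bool = False  # ridge-stabilized because a cell separated

    @property
    def coef(self) -> pd.Series:
        return self.summary.set_index("covariate")["coef"]


def fit_cox(X: pd.DataFrame, durations, events, tol: float = 1e-9,
            max_iter: int = 100, ridge: float = 0.0) -> CoxFitResult:
    """Efron Cox fit by Newton-Raphson with step-halving.

    Raises :class:`ConvergenceError` naming the offending covariate on a
    monotone likelihood (perfect separation) and on a singular
    information matrix (collinearity).  ``ridge`` adds an L2 penalty
    0.5*ridge*||beta||^2 to stabilize refits on bootstrap resamples
    whose small cells lose all their events; penalized fits skip the
    monotone-likelihood guard because the penalty bounds the optimum.
    """
    Xm = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(Xm.shape[1])]
    T = np.asarray(durations, float)
    E = np.asarray(events, bool)
    if E.sum() < 1:
        raise ValueError("need at least one event")
    const = np.ptp(Xm, axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate {names[int(np.flatnonzero(const)[0])]!r}")
    # center for numerical stability; coefficients unaffected
    Xc = Xm - Xm.mean(axis=0)
    p_dim = Xm.shape[1]

    def _objective(b):
        ll, grad, hess = _efron_loglik_grad_hess(b, Xc, T, E)
        if ridge > 0:
            ll -= 0.5 * ridge * float(b @ b)
            grad = grad - ridge * b
            hess = hess - ridge * np.eye(p_dim)
        return ll, grad, hess

    beta = np.zeros(p_dim)
    ll, grad, hess = _objective(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            j = int(np.abs(np.diag(hess)).argmin())
            raise ConvergenceError(
                f"singular information matrix (collinear covariate {names[j]!r})")
        # step-halving keeps the partial likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _objective(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # |beta| > 20 (HR ~ 5e8) only happens when the likelihood is monotone
        if ridge == 0 and np.abs(beta).max() > 20:
            j = int(np.abs(beta).argmax())
            raise ConvergenceError(
                f"monotone likelihood: covariate {names[j]!r} separates the events")
        if np.linalg.norm(grad) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular information matrix at the optimum")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame({
        "covariate": names,
        "coef": beta,
        "se": se,
        "hr": np.exp(beta),
        "ci_low": np.exp(np.clip(beta - 1.96 * se, -700, 700)),
        "ci_high": np.exp(np.clip(beta + 1.96 * se, -700, 700)),
        "p": pvals,
    })
    d = int(E.sum())
    p_dim = Xm.shape[1]
    return CoxFitResult(summary, float(ll), -2 * ll + 2 * p_dim,
                        -2 * ll + p_dim * np.log(d), len(T), d, n_iter=n_iter)


def fit_cox_stabilized(X: pd.DataFrame, durations, events, **kwargs) -> CoxFitResult:
    """Cox fit that falls back to a light ridge when a cell separates.

    A subphenotype with no observed events (small clusters genuinely
    have very few) makes the unpenalized likelihood monotone; the
    stabilized refit is flagged via ``penalized``.
    """
    try:
        return fit_cox(X, durations, events, **kwargs)
    except ConvergenceError:
        res = fit_cox(X, durations, events, ridge=0.1, **kwargs)
        res.penalized = True
        return res


def harrell_c(scores, durations, events) -> float:
    """Concordance over usable pairs; tied risk scores count 1/2.

    A pair is usable when censoring leaves the failure order
    determinable: the earlier time is an observed event and the times
    differ.
    """
    s = np.asarray(scores, float)
    T = np.asarray(durations, float)
    E = np.asarray(events, bool)
    usable = (T[:, None] < T[None, :]) & E[:, None]
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs for the concordance index")
    conc = (s[:, None] > s[None, :]) & usable
    tied = (s[:, None] == s[None, :]) & usable
    return float((conc.sum() + 0.5 * tied.sum()) / n_pairs)


def optimism_corrected_c(X: pd.DataFrame, durations, events, B: int = 200,
                         seed: int = 0) -> tuple[float, float]:
    """Harrell's bias-corrected C: apparent C minus mean bootstrap optimism."""
    T = np.asarray(durations, float)
    E = np.asarray(events, bool)
    full = fit_cox_stabilized(X, T, E)
    risk_full = X.to_numpy(float) @ full.coef.to_numpy()
    apparent = harrell_c(risk_full, T, E)
    rng = np.random.default_rng(seed)
    optimism = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(len(T), size=len(T))
        try:
            boot = fit_cox(X.iloc[idx], T[idx], E[idx])
        except (ConvergenceError, ValueError):
            # a resample that empties a small cell separates; a light ridge
            # keeps the refit usable (standard internal-validation practice)
            try:
                boot = fit_cox(X.iloc[idx], T[idx], E[idx], ridge=0.1)
            except (ConvergenceError, ValueError):
                failures += 1
                continue
        b = boot.coef.to_numpy()
        c_boot = harrell_c(X.to_numpy(float)[idx] @ b, T[idx], E[idx])
        c_orig = harrell_c(X.to_numpy(float) @ b, T, E)
        optimism.append(c_boot - c_orig)
    if failures > 0.1 * B:
        raise ConvergenceError(
            f"{failures}/{B} bootstrap Cox fits failed; data too unstable for "
            "optimism correction")
    corrected = apparent - float(np.mean(optimism)) if optimism else apparent
    return apparent, corrected


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

def kaplan_meier_logrank(outcomes: pd.DataFrame, labels: pd.Series):
    """Product-limit curves per group and the K-group log-rank test.

    Returns (curves, chi2, df, p) where ``curves`` maps group ->
    DataFrame(time, n_at_risk, survival).
    """
    df = outcomes.set_index("patient_id")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    T = df["time_to_event_years"].to_numpy(float)
    E = df["event"].to_numpy(bool)
    G = labels.loc[df.index].to_numpy()
    for g in groups:
        if (G == g).sum() == 0:
            raise ValueError(f"group {g} has no subjects")
    if E.sum() < 1:
        raise ValueError("need at least one event")

    curves = {}
    for g in groups:
        tg, eg = T[G == g], E[G == g]
        times = np.unique(tg[eg])
        s = 1.0
        rows = []
        for t in times:
            at_risk = int((tg >= t).sum())
            d = int(((tg == t) & eg).sum())
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, s))
        curves[g] = pd.DataFrame(rows, columns=["time", "n_at_risk", "survival"])

    k = len(groups)
    event_times = np.unique(T[E])
    O = np.zeros(k)
    Ex = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = T >= t
        n_t = int(at_risk.sum())
        d_t = int((E & (T == t)).sum())
        n_g = np.array([(at_risk & (G == g)).sum() for g in groups], float)
        d_g = np.array([((T == t) & E & (G == g)).sum() for g in groups], float)
        O += d_g
        Ex += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - Ex)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    dof = k - 1
    p = float(stats.chi2.sf(chi2, dof))
    return curves, chi2, dof, p


# ---------------------------------------------------------------------------
# clinical comparisons and model-3 covariate selection

@dataclass
class ClinicalComparison:
    variable: str
    test: str                    # kruskal_wallis | chi_square | fisher_exact
    statistic: float
    p: float
    summaries: pd.DataFrame      # per-group median/IQR or count/percent


def _contingency(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    cats = np.unique(values)
    gs = np.unique(groups)
    return np.array([[(values[groups == g] == c).sum() for c in cats] for g in gs],
                    float)


def _fisher_mc_p(table: np.ndarray, n_sim: int = 10000, seed: int = 0) -> float:
    """Conditional Monte-Carlo exact test for r x c tables (fixed margins),
    using the chi-square statistic as the ordering criterion."""
    rng = np.random.default_rng(seed)
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    exp = np.outer(rows, cols) / table.sum()
    obs_stat = ((table - exp) ** 2 / np.where(exp > 0, exp, 1)).sum()
    pool = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_sim):
        rng.shuffle(pool)
        sim = np.zeros_like(table)
        start = 0
        for i, r in enumerate(rows):
            seg = pool[start:start + r]
            sim[i] = np.bincount(seg, minlength=len(cols))
            start += r
        stat = ((sim - exp) ** 2 / np.where(exp > 0, exp, 1)).sum()
        hits += stat >= obs_stat - 1e-12
    return (hits + 1) / (n_sim + 1)


def _categorical_test(values, groups, seed: int = 0) -> tuple[str, float, float]:
    table = _contingency(np.asarray(values), np.asarray(groups))
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        if table.shape == (2, 2):
            odds, p = stats.fisher_exact(table.astype(int))
            return "fisher_exact", float(odds), float(p)
        return "fisher_exact", np.nan, _fisher_mc_p(table, seed=seed)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi_square", float(chi2), float(p)


def compare_clinical(clinical: ClinicalTable, labels: pd.Series,
                     seed: int = 0) -> list[ClinicalComparison]:
    """Test every clinical variable across the subphenotypes.

    Numeric variables use Kruskal-Wallis; binary/categorical use
    chi-square, falling back to Fisher's exact test when any expected
    cell is below 5.  Single-valued variables are skipped.
    """
    df = clinical.data.set_index("patient_id").loc[labels.index]
    groups = labels.to_numpy()
    out: list[ClinicalComparison] = []
    for var in clinical.variables:
        vals = df[var].to_numpy()
        if len(pd.unique(vals)) < 2:
            continue
        kind = clinical.types.get(var, "numeric")
        if kind == "numeric":
            h, _, p = kruskal_wallis(vals.astype(float), groups)
            summ = df.groupby(groups)[var].describe()[["50%", "25%", "75%"]]
            summ.columns = ["median", "q1", "q3"]
            out.append(ClinicalComparison(var, "kruskal_wallis", h, p, summ.reset_index()))
        else:
            test, statv, p = _categorical_test(vals, groups, seed=seed)
            counts = pd.crosstab(groups, vals)
            pct = counts.div(counts.sum(axis=1), axis=0)
            summ = pd.concat({"count": counts, "fraction": pct}, axis=1).reset_index()
            out.append(ClinicalComparison(var, test, statv, p, summ))
    return out


FORCED_TRIO = ("age", "sex", "egfr")


def select_model3_covariates(clinical: ClinicalTable, outcomes: pd.DataFrame,
                             alpha: float = 0.05, seed: int = 0) -> list[str]:
    """Data-driven model-3 covariate set.

    Every clinical variable is tested against endpoint occurrence
    (numeric: Kruskal-Wallis by event status; categorical: chi-square or
    Fisher), p-values are BH-corrected across variables, and the
    variables with q <= alpha are kept — with age, sex and eGFR always
    forced into the model.
    """
    df = clinical.data.set_index("patient_id")
    out = outcomes.set_index("patient_id").loc[df.index]
    event = out["event"].to_numpy(bool)
    names, pvals = [], []
    for var in clinical.variables:
        vals = df[var].to_numpy()
        if len(pd.unique(vals)) < 2:
            continue
        kind = clinical.types.get(var, "numeric")
        if kind == "numeric":
            _, _, p = kruskal_wallis(vals.astype(float), event.astype(int))
        else:
            _, _, p = _categorical_test(vals, event.astype(int), seed=seed)
        names.append(var)
        pvals.append(p)
    _, reject = bh_adjust(np.asarray(pvals), alpha)
    selected = [v for v, r in zip(names, reject) if r]
    for forced in FORCED_TRIO:
        if forced in clinical.variables and forced not in selected:
            selected.append(forced)
    return sorted(selected)


def cox_design(clinical: ClinicalTable, labels: pd.Series, spec: CoxModelSpec,
               log_ntprobnp: bool = True) -> pd.DataFrame:
    """Design matrix: subphenotype dummies vs the reference + covariates."""
    df = clinical.data.set_index("patient_id").loc[labels.index]
    design = pd.DataFrame(index=labels.index)
    for c in sorted(labels.unique()):
        if c == spec.reference_cluster:
            continue
        design[f"cluster_{c}"] = (labels == c).astype(float)
    for var in spec.covariates:
        if var == "ntprobnp" and log_ntprobnp:
            design["log_ntprobnp"] = np.log(df[var].astype(float))
        elif clinical.types.get(var) == "categorical":
            for val in sorted(pd.unique(df[var]))[1:]:
                design[f"{var}_{val}"] = (df[var] == val).astype(float)
        else:
            design[var] = df[var].astype(float)
    return design


def fit_adjustment_levels(clinical: ClinicalTable, outcomes: pd.DataFrame,
                          labels: pd.Series, B: int = 200, seed: int = 0,
                          alpha: float = 0.05,
                          levels: tuple[int, ...] = (1, 2, 3, 4)) -> dict[int, CoxFitResult]:
    """Fit the pre-specified adjustment levels with corrected C."""
    out = outcomes.set_index("patient_id").loc[labels.index]
    T = out["time_to_event_years"].to_numpy(float)
    E = out["event"].to_numpy(bool)
    model3 = select_model3_covariates(clinical, outcomes, alpha=alpha, seed=seed) \
        if {3, 4} & set(levels) else []
    covsets = {
        1: [],
        2: list(FORCED_TRIO),
        3: model3,
        4: model3 + ["ntprobnp"],
    }
    rng = np.random.default_rng(seed)
    results = {}
    for level, covs in covsets.items():
        if level not in levels:
            continue
        covs = [c for c in covs if c in clinical.variables]
        spec = CoxModelSpec(level=level, covariates=covs)
        X = cox_design(clinical, labels, spec)
        res = fit_cox_stabilized(X, T, E)
        app, corr = optimism_corrected_c(X, T, E, B=B, seed=int(rng.integers(2**31)))
        res.apparent_c, res.corrected_c, res.bootstrap_b = app, corr, B
        results[level] = res
    return results
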