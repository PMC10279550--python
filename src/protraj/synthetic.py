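"""Synthetic longitudinal proteomic cohorts with known ground truth.

The generator emulates a chronic heart-failure biomarker study: patients
are sampled at baseline and then trimonthly (with small scheduling
jitter) until a clinical event or censoring; a large aptamer panel is
measured at every visit.  K latent subphenotypes differ in the mean
level (intercept) and yearly change (slope) of protein subsets; event
times follow an exponential proportional-hazards model with
subphenotype-specific hazard ratios; clinical covariates are shifted by
subphenotype.

Proteins inherit their subphenotype contrast from the subset they belong
to; on top of the subset mean, each (patient, protein) pair has its own
Gaussian random intercept and slope, plus log-normal measurement noise
per visit.  RFU readouts are emitted as ``1000 * exp(latent log-value)``
so the downstream log/Z-score path is exercised nontrivially.

The default configuration built by :func:`default_config` encodes the
study conditions used throughout the test-suite: K = 4 subphenotypes
whose subset-mean profiles lie on two latent axes (so the cluster means
are affinely rank-2), mixing weights proportional to the reported
cluster sizes of the motivating cohort, ~30% event rate, and decoy
aptamers (non-human, non-validated, duplicate-target) mirroring the
fraction the real assay's annotation filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_formats import ClinicalTable

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "CohortData",
    "default_config",
    "generate_cohort",
    "truth_alignment",
]


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    n_patients: int
    n_proteins: int
    k_true: int
    mixing: np.ndarray                  # length k_true, sums to 1
    n_subsets: int
    subset_sizes: np.ndarray            # length n_subsets, sums to n_proteins
    intercept_effects: np.ndarray       # (n_subsets, k_true) mean latent intercepts
    slope_effects: np.ndarray           # (n_subsets, k_true) mean latent slopes / year
    re_sd_intercept: float = 0.5        # between-patient SD of protein intercepts
    re_sd_slope: float = 0.25           # between-patient SD of protein slopes (per year)
    resid_sd: float = 0.5               # visit-level log-normal measurement noise SD
    visit_interval_years: float = 0.25  # trimonthly scheduling
    visit_jitter_sd: float = 0.02       # ~1 week jitter, mimics "(+/- 1 month)" windows
    max_followup_years: float = 2.7
    log_hr: np.ndarray = None           # length k_true, first entry 0
    baseline_hazard: float = 0.07       # events/year in the reference subphenotype
                                        # (~30% overall event rate with the
                                        # default hazard ratios and follow-up)
    admin_censor_years: float = 2.7
    censor_uniform_low: float = 1.0     # staggered-entry censoring ~ U(low, admin)
    n_decoy_nonhuman: int = 0
    n_decoy_unvalidated: int = 0
    n_duplicate_targets: int = 0
    clinical_shifts: dict = field(default_factory=dict)  # var -> length-k shift vector
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.subset_sizes = np.asarray(self.subset_sizes, dtype=int)
        self.intercept_effects = np.asarray(self.intercept_effects, dtype=float)
        self.slope_effects = np.asarray(self.slope_effects, dtype=float)
        if self.log_hr is None:
            self.log_hr = np.zeros(self.k_true)
        self.log_hr = np.asarray(self.log_hr, dtype=float)
        if self.mixing.shape != (self.k_true,):
            raise ConfigError("mixing must have length k_true")
        if abs(self.mixing.sum() - 1.0) > 1e-9:
            raise ConfigError(f"mixing sums to {self.mixing.sum()}, not 1")
        if self.subset_sizes.shape != (self.n_subsets,):
            raise ConfigError("subset_sizes must have length n_subsets")
        if int(self.subset_sizes.sum()) != self.n_proteins:
            raise ConfigError("subset_sizes must sum to n_proteins")
        if self.intercept_effects.shape != (self.n_subsets, self.k_true):
            raise ConfigError("intercept_effects must be (n_subsets, k_true)")
        if self.slope_effects.shape != (self.n_subsets, self.k_true):
            raise ConfigError("slope_effects must be (n_subsets, k_true)")
        if self.log_hr.shape != (self.k_true,) or self.log_hr[0] != 0.0:
            raise ConfigError("log_hr must have length k_true with log_hr[0] == 0")
        for name in ("re_sd_intercept", "re_sd_slope", "resid_sd", "visit_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("visit_interval_years", "max_followup_years", "baseline_hazard",
                     "admin_censor_years"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, (np.integer, np.floating)):
                d[k] = v.item()
        d["clinical_shifts"] = {k: np.asarray(v, float).tolist() for k, v in
                                self.clinical_shifts.items()}
        return d


@dataclass
class SyntheticTruth:
    subphenotype: pd.Series      # patient_id -> 1..k_true
    protein_subset: pd.Series    # seq_id -> 0..n_subsets-1 (structured proteins only)
    event_time: pd.Series        # patient_id -> latent event time (uncensored)
    censor_time: pd.Series       # patient_id -> censoring time


class CohortData(NamedTuple):
    long: pd.DataFrame
    clinical: ClinicalTable
    outcomes: pd.DataFrame
    annotation: pd.DataFrame
    truth: SyntheticTruth


# The four subphenotype mean profiles sit on the corners of a square in a
# two-dimensional latent "biology" space; informative subsets load on one
# of the two axes.  Rows: subsets; columns: subphenotypes.
_AXIS_X4 = np.array([-0.5, 0.5, -0.5, 0.5])
_AXIS_Y4 = np.array([-0.5, -0.5, 0.5, 0.5])


def default_config(
    n_patients: int = 400,
    n_proteins: int = 500,
    k_true: int = 4,
    separation: float = 1.5,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Build the default study conditions.

    ``separation`` scales subset-mean contrasts so that adjacent
    subphenotypes differ by ``separation`` within-subphenotype latent
    SDs on each informative subset axis.
    """
    re_sd_i = overrides.pop("re_sd_intercept", 0.5)
    re_sd_s = overrides.pop("re_sd_slope", 0.25)
    if k_true == 4:
        ax, ay = _AXIS_X4, _AXIS_Y4
        mixing = np.array([90.0, 121.0, 128.0, 43.0])
        log_hr = np.array([0.0, np.log(3.4), np.log(2.9), np.log(1.3)])
    else:
        grid = np.linspace(-0.5, 0.5, k_true)
        ax, ay = grid, grid[::-1]
        mixing = np.ones(k_true)
        log_hr = np.concatenate([[0.0], np.linspace(0.8, 1.2, k_true - 1)])
    mixing = mixing / mixing.sum()

    n_subsets = 4
    # subset sizes proportional to the reported intercept-subset sizes
    frac = np.array([1054.0, 897.0, 643.0, 1615.0])
    sizes = np.floor(frac / frac.sum() * n_proteins).astype(int)
    sizes[-1] += n_proteins - sizes.sum()
    # subsets A,B load on axis x; subset D on axis y; subset C carries no signal
    icpt = separation * re_sd_i * np.vstack([ax, ax, np.zeros(k_true), ay])
    slope = separation * re_sd_s * np.vstack([ay, np.zeros(k_true), np.zeros(k_true), ax])
    shifts = {
        "age": -8.0 * ay,          # reference-side subphenotypes older
        "sbp": -10.0 * ax,
        "egfr": 12.0 * ay,
        "log_ntprobnp": np.array([0.0, 0.9, -0.3, -0.3])[:k_true] if k_true == 4
        else 0.5 * ax,
        "chronic_renal_failure": 0.3 * ax,
        "diabetes": 0.25 * ax,
        "nyha_12": -0.2 * ax,
        "atrial_fibrillation": 0.25 * ay,
    }
    cfg = dict(
        n_patients=n_patients,
        n_proteins=n_proteins,
        k_true=k_true,
        mixing=mixing,
        n_subsets=n_subsets,
        subset_sizes=sizes,
        intercept_effects=icpt,
        slope_effects=slope,
        re_sd_intercept=re_sd_i,
        re_sd_slope=re_sd_s,
        log_hr=log_hr,
        n_decoy_nonhuman=max(1, round(0.036 * n_proteins)) if n_proteins >= 20 else 0,
        n_decoy_unvalidated=max(1, round(0.036 * n_proteins)) if n_proteins >= 20 else 0,
        n_duplicate_targets=max(1, round(0.18 * n_proteins)) if n_proteins >= 20 else 0,
        clinical_shifts=shifts,
        seed=seed,
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


def _visit_times(rng: np.random.Generator, followup: float, interval: float,
                 jitter_sd: float, max_followup: float) -> np.ndarray:
    """Baseline plus jittered trimonthly visits while on study."""
    end = min(followup, max_followup)
    times = [0.0]
    j = 1
    while True:
        t = j * interval + rng.normal(0.0, jitter_sd)
        t = max(t, times[-1] + 1e-3)  # keep strictly increasing
        if t > end:
            break
        times.append(t)
        j += 1
    return np.asarray(times)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Draw a full cohort; identical configs and seeds give identical tables."""
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_patients, config.n_proteins, config.k_true

    patient_ids = np.array([f"P{i:04d}" for i in range(n)])
    z = rng.choice(k, size=n, p=config.mixing)  # 0-based subphenotype

    # survival: exponential event times, staggered-entry + administrative censoring
    rate = config.baseline_hazard * np.exp(config.log_hr[z])
    event_time = rng.exponential(1.0 / rate)
    lo = min(config.censor_uniform_low, config.admin_censor_years)
    censor_time = rng.uniform(lo, config.admin_censor_years, size=n)
    followup = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    followup = np.maximum(followup, 1e-3)

    # visit schedule
    visit_times = [
        _visit_times(rng, followup[i], config.visit_interval_years,
                     config.visit_jitter_sd, config.max_followup_years)
        for i in range(n)
    ]
    n_visits = np.array([len(v) for v in visit_times])
    t_all = np.concatenate(visit_times)                       # (total_rows,)
    pat_idx = np.repeat(np.arange(n), n_visits)

    # protein panel
    subset_of_protein = np.repeat(np.arange(config.n_subsets), config.subset_sizes)
    seq_ids = np.array([f"SQ{j:05d}" for j in range(p)])

    b0 = rng.normal(0.0, config.re_sd_intercept, size=(n, p))
    b1 = rng.normal(0.0, config.re_sd_slope, size=(n, p))
    mu0 = config.intercept_effects[subset_of_protein][:, z].T  # (n, p)
    mu1 = config.slope_effects[subset_of_protein][:, z].T
    icpt = mu0 + b0
    slp = mu1 + b1
    latent = icpt[pat_idx] + slp[pat_idx] * t_all[:, None]
    latent = latent + rng.normal(0.0, config.resid_sd, size=latent.shape)

    # decoy aptamers: pure-noise non-human / non-validated reagents, plus
    # duplicate-target reagents (weaker affinity copies of real proteins)
    n_nh, n_nv, n_dup = (config.n_decoy_nonhuman, config.n_decoy_unvalidated,
                         config.n_duplicate_targets)
    n_decoy = n_nh + n_nv + n_dup
    decoy_ids = np.array([f"SQ{p + j:05d}" for j in range(n_decoy)])
    if n_decoy:
        decoy_latent = rng.normal(0.0, 1.0, size=(latent.shape[0], n_decoy))
        dup_src = rng.choice(p, size=n_dup) if n_dup else np.empty(0, int)
        if n_dup:
            decoy_latent[:, n_nh + n_nv:] = latent[:, dup_src] + rng.normal(
                0.0, 0.3, size=(latent.shape[0], n_dup))
        latent = np.concatenate([latent, decoy_latent], axis=1)
    else:
        dup_src = np.empty(0, int)

    all_ids = np.concatenate([seq_ids, decoy_ids])
    p_tot = len(all_ids)
    rfu = 1000.0 * np.exp(latent)

    sample_ids = np.array([f"{patient_ids[pat_idx[r]]}-V{v:02d}"
                           for r, v in enumerate(_visit_numbers(n_visits))])
    long = pd.DataFrame(
        {
            "patient_id": pd.Categorical(np.repeat(patient_ids[pat_idx], p_tot)),
            "sample_id": pd.Categorical(np.repeat(sample_ids, p_tot)),
            "time_years": np.repeat(t_all, p_tot),
            "seq_id": pd.Categorical(np.tile(all_ids, len(t_all))),
            "rfu": rfu.ravel(),
        }
    )

    # annotation: real proteins are human, validated, unique targets, Kd ~ lognormal
    kd = np.exp(rng.normal(0.0, 1.0, size=p_tot))
    target = np.array([f"TGT{j:05d}" for j in range(p_tot)], dtype=object)
    is_human = np.ones(p_tot, bool)
    is_validated = np.ones(p_tot, bool)
    if n_decoy:
        is_human[p:p + n_nh] = False
        is_validated[p + n_nh:p + n_nh + n_nv] = False
        if n_dup:
            target[p + n_nh + n_nv:] = [f"TGT{j:05d}" for j in dup_src]
            kd[p + n_nh + n_nv:] = kd[dup_src] * (1.0 + rng.uniform(0.5, 5.0, n_dup))
    annotation = pd.DataFrame(
        {"seq_id": all_ids, "target_id": target, "is_human": is_human,
         "is_validated": is_validated, "affinity_kd": kd}
    )

    clinical = _clinical_table(rng, patient_ids, z, config)
    outcomes = pd.DataFrame(
        {"patient_id": patient_ids, "time_to_event_years": np.minimum(event_time, censor_time),
         "event": event}
    )
    truth = SyntheticTruth(
        subphenotype=pd.Series(z + 1, index=patient_ids, name="subphenotype"),
        protein_subset=pd.Series(subset_of_protein, index=seq_ids, name="subset"),
        event_time=pd.Series(event_time, index=patient_ids, name="event_time"),
        censor_time=pd.Series(censor_time, index=patient_ids, name="censor_time"),
    )
    return CohortData(long, clinical, outcomes, annotation, truth)


def _visit_numbers(n_visits: np.ndarray) -> np.ndarray:
    return np.concatenate([np.arange(m) for m in n_visits])


def _clinical_table(rng: np.random.Generator, patient_ids: np.ndarray,
                    z: np.ndarray, config: CohortConfig) -> ClinicalTable:
    n = len(patient_ids)
    sh = {k: np.asarray(v, float) for k, v in config.clinical_shifts.items()}
    zero = np.zeros(config.k_true)

    def shift(name):
        return sh.get(name, zero)[z]

    def bern(p_base, name):
        p_ = np.clip(p_base + shift(name), 0.02, 0.98)
        return (rng.uniform(size=n) < p_).astype(int)

    data = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": np.round(rng.normal(65.0 + shift("age"), 10.0), 1),
            "sex": bern(0.73, "sex"),  # 1 = male
            "egfr": np.round(np.clip(rng.normal(60.0 + shift("egfr"), 18.0), 8, 130), 1),
            "sbp": np.round(rng.normal(115.0 + shift("sbp"), 16.0), 0),
            "duration_hf": np.round(np.exp(rng.normal(1.3, 0.9, size=n)), 2),
            "nyha_12": bern(0.73, "nyha_12"),  # NYHA class I/II vs III/IV
            "atrial_fibrillation": bern(0.36, "atrial_fibrillation"),
            "other_arrhythmia": bern(0.40, "other_arrhythmia"),
            "chronic_renal_failure": bern(0.48, "chronic_renal_failure"),
            "diabetes": bern(0.26, "diabetes"),
            "ntprobnp": np.round(np.exp(rng.normal(4.8 + shift("log_ntprobnp"), 1.1, n)), 1),
        }
    )
    types = {
        "age": "numeric", "sex": "binary", "egfr": "numeric", "sbp": "numeric",
        "duration_hf": "numeric", "nyha_12": "binary", "atrial_fibrillation": "binary",
        "other_arrhythmia": "binary", "chronic_renal_failure": "binary",
        "diabetes": "binary", "ntprobnp": "numeric",
    }
    return ClinicalTable(data, types)


def truth_alignment(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items to compare labelings")
    return float(adjusted_rand_score(a, b))
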