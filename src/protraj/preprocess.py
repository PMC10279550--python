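"""Aptamer filtering, analysis-sample selection and log/Z standardization.

The measurement panel is reduced in three deterministic steps: aptamers
with non-human targets are dropped, aptamers with non-validated targets
are dropped, and when several surviving aptamers bind the same protein
only the one with the highest binding affinity (smallest dissociation
constant Kd) is kept.  Per patient, the analysis set is the union of the
baseline sample and the last two samples drawn on or before the
patient's event/censoring time, so each patient contributes 1-3 samples.
Retained values are natural-log transformed and standardized per protein
to Z-scores over the selected samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FilterResult",
    "filter_aptamers",
    "select_samples",
    "LogZScoreScaler",
    "StandardizedSampleMatrix",
    "log_zscore",
]


@dataclass
class FilterResult:
    retained: list[str]
    warnings: list[str] = field(default_factory=list)


def filter_aptamers(annotation: pd.DataFrame) -> FilterResult:
    """Apply the three panel filters; deterministic and idempotent.

    Among same-target survivors the smallest ``affinity_kd`` wins; an
    exact Kd tie is broken toward the lexicographically smallest seq_id
    and recorded as a warning.
    """
    if len(annotation) == 0:
        raise ValueError("empty aptamer annotation")
    ann = annotation[annotation["is_human"] & annotation["is_validated"]]
    warnings: list[str] = []
    retained: list[str] = []
    for target, grp in ann.groupby("target_id", sort=True):
        grp = grp.sort_values(["affinity_kd", "seq_id"], kind="mergesort")
        best_kd = grp["affinity_kd"].iloc[0]
        ties = grp[grp["affinity_kd"] == best_kd]
        if len(ties) > 1:
            warnings.append(
                f"target {target}: affinity tie among {sorted(ties['seq_id'])}; "
                f"kept {ties['seq_id'].iloc[0]}"
            )
        retained.append(grp["seq_id"].iloc[0])
    return FilterResult(sorted(retained), warnings)


def select_samples(long: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Keep, per patient, baseline plus the last two samples before the event.

    The retained set is {baseline} union {the two samples with largest
    time on or before the outcome time}; its size is 1, 2 or 3.
    """
    out = outcomes.set_index("patient_id")["time_to_event_years"]
    missing = set(long["patient_id"].unique()) - set(out.index)
    if missing:
        raise ValueError(f"patients missing from outcome table: {sorted(missing)[:5]}")
    samples = long[["patient_id", "sample_id", "time_years"]].drop_duplicates()
    keep: list[str] = []
    for pid, grp in samples.groupby("patient_id", observed=True, sort=False):
        grp = grp.sort_values("time_years")
        if grp["time_years"].iloc[0] != 0:
            raise ValueError(f"patient {pid!r} lacks a baseline sample")
        horizon = out.loc[pid]
        eligible = grp[grp["time_years"] <= horizon]
        chosen = set(eligible["sample_id"].tail(2))
        chosen.add(grp["sample_id"].iloc[0])
        keep.extend(chosen)
    kept = long[long["sample_id"].isin(keep)].copy()
    if isinstance(kept["sample_id"].dtype, pd.CategoricalDtype):
        kept["sample_id"] = kept["sample_id"].cat.remove_unused_categories()
    return kept.sort_values(["patient_id", "time_years", "seq_id"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class StandardizedSampleMatrix:
    """Z-scores of ln(RFU), samples x proteins.

    ``values`` is indexed by (patient_id, sample_id, time_years);
    ``constants`` stores the per-protein mean and sample SD (ddof=1) of
    the log values so the transform can be inverted exactly; proteins
    with zero variance are dropped and listed in ``warnings``.
    """

    values: pd.DataFrame
    constants: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def patients(self) -> np.ndarray:
        return self.values.index.get_level_values("patient_id").unique().to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.values.index.get_level_values("time_years").to_numpy()


class LogZScoreScaler(BaseEstimator, TransformerMixin):
    """Per-protein natural-log + Z-score transformer over a long table.

    ``fit`` pivots the long table to a samples-by-proteins matrix of
    ln(RFU) and learns per-protein mean/SD; ``transform`` returns a
    :class:`StandardizedSampleMatrix`.  Constant proteins are dropped at
    fit time with a warning record (a degenerate marker carries no
    signal and would divide by zero).
    """

    def __init__(self, retained: list[str] | None = None):
        self.retained = retained

    def _pivot(self, long: pd.DataFrame) -> pd.DataFrame:
        df = long
        if self.retained is not None:
            df = df[df["seq_id"].isin(self.retained)]
            if isinstance(df["seq_id"].dtype, pd.CategoricalDtype):
                df = df.copy()
                df["seq_id"] = df["seq_id"].cat.remove_unused_categories()
        wide = df.pivot_table(
            index=["patient_id", "sample_id", "time_years"],
            columns="seq_id", values="rfu", aggfunc="first", observed=True,
        )
        if wide.isna().any().any():
            raise ValueError("long table is not rectangular after pivoting")
        return np.log(wide)

    def fit(self, long: pd.DataFrame, y=None):
        logw = self._pivot(long)
        mean = logw.mean(axis=0)
        sd = logw.std(axis=0, ddof=1)
        self.warnings_ = [
            f"protein {c}: zero variance across selected samples; column dropped"
            for c in logw.columns[sd <= 0]
        ]
        keep = sd > 0
        self.columns_ = logw.columns[keep]
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        return self

    def transform(self, long: pd.DataFrame) -> StandardizedSampleMatrix:
        logw = self._pivot(long)[self.columns_]
        z = (logw - self.mean_) / self.sd_
        constants = pd.DataFrame({"mean": self.mean_, "sd": self.sd_})
        return StandardizedSampleMatrix(z, constants, list(self.warnings_))

    def inverse_transform(self, matrix: StandardizedSampleMatrix) -> pd.DataFrame:
        """Recover ln(RFU) from Z-scores using the stored constants."""
        return matrix.values * self.sd_ + self.mean_


def log_zscore(long: pd.DataFrame, retained: list[str] | None = None) -> StandardizedSampleMatrix:
    """One-shot fit+transform convenience wrapper over :class:`LogZScoreScaler`."""
    scaler = LogZScoreScaler(retained=retained)
    return scaler.fit(long).transform(long)
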