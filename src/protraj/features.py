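"""Patient-level trajectory feature matrices for clustering.

In repeated-measures mode every protein's standardized longitudinal
values are fed through the REML mixed-effects engine and each patient
receives a BLUP intercept and slope per protein; the resulting
``n_patients x 2P`` block matrix ``[intercepts | slopes]`` is
re-standardized column-wise so that slope columns (which have much
smaller raw variance) contribute comparably to distance-based
clustering.  In single-visit mode the matrix is simply the standardized
protein values at the chosen visit (baseline, second or last), which is
how single-timepoint cluster analyses are run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lme import LMEDesign, LMEFit, reml_fit
from .preprocess import StandardizedSampleMatrix

__all__ = ["LMETrajectoryFeaturizer", "assemble_feature_matrix", "single_visit_matrix"]


def _standardize_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    sd = sd.where(sd > 0, 1.0)  # constant feature column: leave centered at 0
    return (df - mean) / sd, pd.DataFrame({"mean": mean, "sd": sd})


class LMETrajectoryFeaturizer(BaseEstimator, TransformerMixin):
    """Per-protein mixed models -> per-patient (intercept, slope) features.

    Parameters
    ----------
    tol, max_iter : REML convergence tolerance on successive criterion
        values and the iteration cap.
    slope_var_floor : below this random-slope variance the protein is
        refitted as random-intercept-only (1-3 visits per patient can
        leave the slope variance unidentifiable).

    Attributes (after ``fit``)
    --------------------------
    fits_ : dict protein -> :class:`~protraj.lme.LMEFit`
    features_ : raw BLUP feature frame (patients x (feature, protein))
    scale_ : column standardization constants used by ``transform``
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500,
                 slope_var_floor: float = 1e-10):
        self.tol = tol
        self.max_iter = max_iter
        self.slope_var_floor = slope_var_floor

    def fit(self, matrix: StandardizedSampleMatrix, y=None):
        idx = matrix.values.index
        patients = idx.get_level_values("patient_id")
        codes, uniques = pd.factorize(patients, sort=True)
        times = idx.get_level_values("time_years").to_numpy(float)
        design = LMEDesign(np.asarray(codes), times)
        # design sorts patients by code; map back to patient ids
        row_patients = uniques[design.patient_codes]

        self.fits_: dict[str, LMEFit] = {}
        blocks = {}
        vals = matrix.values.to_numpy(float)
        for j, protein in enumerate(matrix.values.columns):
            fit, feats = reml_fit(design, vals[:, j], tol=self.tol,
                                  max_iter=self.max_iter,
                                  slope_var_floor=self.slope_var_floor)
            self.fits_[protein] = fit
            blocks[protein] = feats
        icpt = pd.DataFrame({p: blocks[p][:, 0] for p in matrix.values.columns},
                            index=row_patients)
        slope = pd.DataFrame({p: blocks[p][:, 1] for p in matrix.values.columns},
                             index=row_patients)
        raw = pd.concat({"intercept": icpt, "slope": slope}, axis=1)
        raw.index.name = "patient_id"
        self.features_ = raw
        std, self.scale_ = _standardize_columns(raw)
        self.features_std_ = std
        return self

    def transform(self, X: StandardizedSampleMatrix | None = None) -> pd.DataFrame:
        """Return the standardized feature matrix learned at fit time."""
        return self.features_std_


def single_visit_matrix(matrix: StandardizedSampleMatrix,
                        which: str) -> tuple[pd.DataFrame, list[str]]:
    """Standardized values at one visit per patient (baseline|second|last).

    Patients lacking the requested visit are dropped and reported, which
    mirrors running the per-timepoint analyses on the patients that have
    that measurement.
    """
    if which not in ("baseline", "second", "last"):
        raise ValueError(f"unknown visit selector {which!r}")
    df = matrix.values.reset_index()
    dropped: list[str] = []
    rows = []
    for pid, grp in df.groupby("patient_id", observed=True, sort=True):
        grp = grp.sort_values("time_years")
        if which == "baseline":
            rows.append(grp.iloc[0])
        elif which == "last":
            rows.append(grp.iloc[-1])
        else:  # second
            if len(grp) < 2:
                dropped.append(f"patient {pid}: no second visit; dropped from "
                               "single-visit analysis")
                continue
            rows.append(grp.iloc[1])
    out = pd.DataFrame(rows).set_index("patient_id")
    out = out.drop(columns=["sample_id", "time_years"])
    out.columns.name = None
    std, _ = _standardize_columns(out)
    return std, dropped


def assemble_feature_matrix(
    source,
    mode: str = "repeated",
    which: str = "baseline",
) -> tuple[pd.DataFrame, list[str]]:
    """Build the clustering feature matrix.

    ``mode="repeated"`` expects a fitted :class:`LMETrajectoryFeaturizer`
    (or fits one from a :class:`StandardizedSampleMatrix`) and yields the
    ``n x 2P`` standardized [intercepts | slopes] matrix;
    ``mode="single_visit"`` yields the ``n x P`` standardized values at
    the chosen visit.  Returns (matrix, warning records).
    """
    if mode == "repeated":
        if isinstance(source, LMETrajectoryFeaturizer):
            return source.transform(None), []
        feat = LMETrajectoryFeaturizer().fit(source)
        return feat.transform(None), []
    if mode == "single_visit":
        return single_visit_matrix(source, which)
    raise ValueError(f"unknown mode {mode!r}")
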