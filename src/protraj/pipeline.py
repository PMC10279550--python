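"""End-to-end orchestration: simulate -> preprocess -> features -> cluster ->
stability -> subsets -> survival -> report.

A single :class:`RunConfig` drives the whole run.  Every stochastic
stage draws its seed deterministically from the master seed and the
stage name, so a run is a pure function of (inputs, config): re-running
with the same config reproduces every table byte-for-byte.  When an
output directory is given, the expensive trajectory-feature matrix is
cached (with a config checksum) and reused on resumption.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats
from .cluster import ConsensusClusterer, StabilityReport
from .features import LMETrajectoryFeaturizer, single_visit_matrix
from .preprocess import filter_aptamers, log_zscore, select_samples
from .subsets import cluster_proteins, driver_summary, subset_patient_score
from .survival import compare_clinical, fit_adjustment_levels, kaplan_meier_logrank
from .synthetic import CohortConfig, CohortData, default_config, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_modes",
           "stage_seed"]

log = logging.getLogger("protraj")

STAGES = ["simulate", "preprocess", "features", "cluster", "stability",
          "subsets", "survival", "report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256(master, stage) mod 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    mode: str = "repeated"            # repeated | baseline | second | last
    outdir: str | None = None
    cohort: CohortConfig | None = None  # None with no inputs -> default_config
    inputs: dict | None = None          # paths: long, annotation, clinical, outcomes
    embedding: str = "umap"
    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    k_range: tuple[int, int] = (2, 8)
    bootstrap_b: int = 100
    n_init: int = 25
    gap_b: int = 20
    final_k: int | None = None
    stability_tau: float = 0.1
    stability_repeats: int = 100
    subsets_enabled: bool = True
    cox_bootstrap_b: int = 200
    cox_levels: tuple[int, ...] = (1, 2, 3, 4)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("repeated", "baseline", "second", "last"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.k_range = tuple(self.k_range)
        self.cox_levels = tuple(self.cox_levels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        d["k_range"] = list(self.k_range)
        d["cox_levels"] = list(self.cox_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig(**{
                k: v for k, v in d["cohort"].items()})
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: CohortData | None
    retained: list[str]
    features: pd.DataFrame
    clusterer: ConsensusClusterer
    stability: StabilityReport | None
    partitions: dict
    drivers: dict
    subset_scores: dict
    survival: dict
    clinical_comparisons: list
    logrank: tuple
    manifest: dict

    @property
    def labels(self) -> pd.Series:
        return self.clusterer.solution_.labels


def _load_inputs(cfg: RunConfig) -> CohortData:
    paths = cfg.inputs
    long = io_formats.read_long_protein_table(paths["long"])
    annotation = io_formats.read_annotation(paths["annotation"])
    clinical = io_formats.read_clinical(paths["clinical"])
    outcomes = io_formats.read_outcomes(paths["outcomes"])
    return CohortData(long, clinical, outcomes, annotation, None)


def run_pipeline(config: RunConfig, until: str = "report") -> PipelineResult:
    """Execute the stages in order, stopping after ``until``."""
    seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    manifest: dict = {
        "config": config.to_dict(), "seeds": seeds, "stages": [],
        "warnings": [], "time_unit": "years", "log_base": "natural",
    }
    stop = STAGES.index(until)

    def done(stage: str):
        manifest["stages"].append(stage)
        log.info(json.dumps({"stage": stage, "status": "completed"}))

    # -- simulate / load ----------------------------------------------------
    if config.inputs is not None:
        cohort = _load_inputs(config)
    else:
        ccfg = config.cohort or default_config()
        ccfg = dataclasses.replace(ccfg, seed=seeds["simulate"])
        cohort = generate_cohort(ccfg)
    done("simulate")
    result = dict(cohort=cohort, retained=[], features=pd.DataFrame(),
                  clusterer=None, stability=None, partitions={}, drivers={},
                  subset_scores={}, survival={}, clinical_comparisons=[],
                  logrank=())
    if stop <= STAGES.index("simulate"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- preprocess ---------------------------------------------------------
    filt = filter_aptamers(cohort.annotation)
    manifest["warnings"] += filt.warnings
    selected = select_samples(cohort.long, cohort.outcomes)
    smatrix = log_zscore(selected, retained=filt.retained)
    manifest["warnings"] += smatrix.warnings
    result["retained"] = filt.retained
    done("preprocess")
    if stop <= STAGES.index("preprocess"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- features (cached when an outdir is configured) ---------------------
    cache = None
    if config.outdir:
        cache = Path(config.outdir) / f"features_{config.mode}_{config.config_hash()}.tsv"
    featurizer = None
    if config.mode == "repeated":
        if cache is not None and cache.exists():
            features = pd.read_csv(cache, sep="\t", header=[0, 1], index_col=0)
            log.info(json.dumps({"stage": "features", "status": "cache hit"}))
        else:
            featurizer = LMETrajectoryFeaturizer().fit(smatrix)
            features = featurizer.transform(None)
            if cache is not None:
                cache.parent.mkdir(parents=True, exist_ok=True)
                features.to_csv(cache, sep="\t")
    else:
        features, dropped = single_visit_matrix(smatrix, config.mode)
        manifest["warnings"] += dropped
    result["features"] = features
    done("features")
    if stop <= STAGES.index("features"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- cluster ------------------------------------------------------------
    clusterer = ConsensusClusterer(
        method=config.embedding, n_components=config.n_components,
        n_neighbors=config.n_neighbors, min_dist=config.min_dist,
        k_range=config.k_range, B=config.bootstrap_b, final_k=config.final_k,
        n_init=config.n_init, gap_b=config.gap_b, seed=seeds["cluster"],
    ).fit(features)
    result["clusterer"] = clusterer
    labels = clusterer.solution_.labels
    done("cluster")
    if stop <= STAGES.index("cluster"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- stability ----------------------------------------------------------
    if config.stability_repeats > 0:
        result["stability"] = clusterer.stability_report(
            features, tau=config.stability_tau, repeats=config.stability_repeats,
            seed=seeds["stability"])
    done("stability")
    if stop <= STAGES.index("stability"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- protein subsets (repeated mode only: needs both axes) --------------
    if config.subsets_enabled and config.mode == "repeated":
        for axis in ("intercept", "slope"):
            part = cluster_proteins(features, axis, k_range=config.k_range,
                                    seed=stage_seed(config.seed, f"subsets:{axis}"),
                                    n_init=config.n_init, gap_b=config.gap_b)
            axis_vals = features[axis]
            result["partitions"][axis] = part
            result["drivers"][axis] = driver_summary(part, axis_vals, labels,
                                                     alpha=config.alpha)
            scores = {}
            for letter in part.sizes:
                proteins = part.labels.index[part.labels == letter]
                scores[letter], _ = subset_patient_score(axis_vals, proteins)
            result["subset_scores"][axis] = pd.DataFrame(scores)
    elif config.subsets_enabled:
        manifest["warnings"].append(
            f"subsets stage skipped in mode {config.mode!r} (needs both axes)")
    done("subsets")
    if stop <= STAGES.index("subsets"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- survival -----------------------------------------------------------
    result["survival"] = fit_adjustment_levels(
        cohort.clinical, cohort.outcomes, labels, B=config.cox_bootstrap_b,
        seed=seeds["survival"], alpha=config.alpha, levels=config.cox_levels)
    result["clinical_comparisons"] = compare_clinical(
        cohort.clinical, labels, seed=seeds["survival"])
    result["logrank"] = kaplan_meier_logrank(cohort.outcomes, labels)
    done("survival")
    if stop <= STAGES.index("survival"):
        return PipelineResult(config, manifest=manifest, **result)

    # -- report -------------------------------------------------------------
    if config.outdir:
        write_bundle(PipelineResult(config, manifest=manifest, **result),
                     config.outdir)
    done("report")
    return PipelineResult(config, manifest=manifest, **result)


def write_bundle(result: PipelineResult, directory: str | Path) -> dict[str, str]:
    """Serialize the run results as the standard report TSVs + manifest."""
    clusterer = result.clusterer
    bundle: dict = {"manifest": result.manifest}
    bundle["cluster_assignments"] = result.labels.rename("cluster").reset_index().rename(
        columns={"index": "patient_id"})
    if clusterer is not None:
        bundle["k_selection_votes"] = clusterer.k_selection_.to_frame()
    if result.stability is not None:
        bundle["stability"] = result.stability.to_frame()
    for axis, drv in result.drivers.items():
        bundle[f"driver_statistics_{axis}"] = drv.per_protein
        bundle[f"driver_subsets_{axis}"] = drv.per_subset
    if result.survival:
        rows = []
        for level, fit in result.survival.items():
            for _, r in fit.summary.iterrows():
                rows.append({"model": level, **r.to_dict(), "aic": fit.aic,
                             "bic": fit.bic, "apparent_c": fit.apparent_c,
                             "corrected_c": fit.corrected_c})
        bundle["survival_summary"] = pd.DataFrame(rows)
    return io_formats.write_report(bundle, directory)


def compare_modes(config: RunConfig, modes: tuple[str, str] = ("repeated", "baseline"),
                  cox_level: int = 1) -> pd.DataFrame:
    """Run two analysis modes on the same simulated cohort and compare
    optimism-corrected C and BIC of the subphenotype survival model.

    Both runs share the master seed, hence the identical cohort; the
    comparison uses the ``cox_level`` adjustment model.
    """
    results = {}
    for mode in modes:
        cfg = dataclasses.replace(config, mode=mode, subsets_enabled=False,
                                  stability_repeats=0, cox_levels=(cox_level,))
        results[mode] = run_pipeline(cfg, until="survival")
    return compare_mode_results(results[modes[0]], results[modes[1]], cox_level)


def compare_mode_results(res_a: PipelineResult, res_b: PipelineResult,
                         cox_level: int = 1) -> pd.DataFrame:
    """Tabulate corrected C / BIC for two completed runs of the same cohort."""
    pa = set(res_a.labels.index)
    pb = set(res_b.labels.index)
    if pa != pb:
        raise ValueError("modes were run on different cohorts (patient sets differ)")
    for r in (res_a, res_b):
        if not r.survival:
            raise ValueError(f"mode {r.config.mode!r} lacks a survival stage")
    rows = []
    for r in (res_a, res_b):
        fit = r.survival[cox_level]
        rows.append({"mode": r.config.mode, "k": r.clusterer.solution_.k,
                     "corrected_c": fit.corrected_c, "apparent_c": fit.apparent_c,
                     "bic": fit.bic, "aic": fit.aic})
    df = pd.DataFrame(rows)
    df.attrs["corrected_c_difference"] = float(
        df["corrected_c"].iloc[0] - df["corrected_c"].iloc[1])
    return df
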