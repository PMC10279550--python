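# protraj

Subphenotyping of longitudinal proteomic cohorts: from repeated protein
measurements to patient clusters with distinct trajectories, driver
protein subsets, and survival association.

## The problem

In chronic diseases such as heart failure with reduced ejection
fraction, patients who share a diagnosis differ widely in underlying
biology and prognosis. Large aptamer-based proteomic panels (thousands
of analytes, RFU readouts) measured repeatedly over follow-up make it
possible to stratify patients not by a protein snapshot but by protein
*trajectories*. `protraj` implements that analysis end-to-end for
biostatisticians and computational biologists:

1. **Preprocessing** — aptamer panel filters (non-human and
   non-validated targets removed; one reagent per protein, keeping the
   smallest dissociation constant K_d), selection of the analysis
   samples (baseline plus the last two samples drawn before the event
   or censoring), natural-log transform and per-protein Z-scoring.
2. **Trajectory features** — one linear mixed-effects model per protein,
   `y_ij = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)·t_ij + ε_ij` with `(b₀ᵢ,b₁ᵢ) ~ N(0, D)`,
   fitted by profiled REML; each patient's features are the BLUP
   intercept and slope `(β₀+b̂₀ᵢ, β₁+b̂₁ᵢ)`.
3. **Consensus clustering** — the feature matrix is embedded (UMAP by
   default; PCA/identity as exact alternatives), the cluster count is
   chosen by an ensemble vote of seven validity indices (silhouette,
   Calinski–Harabasz, Davies–Bouldin, Dunn, C-index, gap statistic,
   Hartigan) on bootstrap resamples, patients are assigned by k-means,
   and stability is quantified by per-cluster Jaccard similarity under
   feature-space noise.
4. **Protein subsets** — proteins are clustered into subsets (separately
   for intercepts and slopes); per-protein Kruskal–Wallis tests against
   the subphenotypes with Benjamini–Hochberg correction identify the
   driving subsets, and per-patient subset scores come from a
   random-intercepts model.
5. **Survival** — Cox proportional-hazards models (Efron ties,
   Newton–Raphson) at four nested adjustment levels, Harrell's C with
   optimism bootstrap correction, Kaplan–Meier/log-rank, and a
   comparison of repeated-measures versus single-visit subphenotypes.

Because cohort data of this kind are not publicly deposited, the package
ships a first-class synthetic-cohort generator with known ground truth
(latent subphenotypes, protein-subset effects, proportional-hazards
event times) so every stage is testable.

## Worked example

```python
from protraj import RunConfig, run_pipeline, default_config, truth_alignment

cfg = RunConfig(
    seed=1,
    cohort=default_config(n_patients=200, n_proteins=80),
    embedding="pca",       # deterministic; "umap" is the default surface
    bootstrap_b=25,
    stability_repeats=25,
)
res = run_pipeline(cfg)

ks = res.clusterer.k_selection_
print("modal k:", ks.modal_k, "votes:", ks.histogram)
truth = res.cohort.truth.subphenotype.loc[res.labels.index]
print("ARI vs truth:", round(truth_alignment(res.labels, truth), 3))
print("Jaccard stability:", {c: round(v, 2)
                             for c, v in res.stability.mean_jaccard.items()})
print("level-1 HRs:", res.survival[1].summary[["covariate", "hr"]].to_dict("records"))
```

prints (seed 1):

```
modal k: 4 votes: {2: 0, 3: 0, 4: 25, 5: 0, 6: 0, 7: 0, 8: 0}
ARI vs truth: 1.0
Jaccard stability: {1: 0.99, 2: 1.0, 3: 0.98, 4: 1.0}
level-1 HRs: [{'covariate': 'cluster_2', 'hr': 1.06},
              {'covariate': 'cluster_3', 'hr': 0.38},
              {'covariate': 'cluster_4', 'hr': 0.51}]
```

All 25 bootstrap resamples chose four clusters; the adjusted Rand index
of 1.0 means the recovered subphenotypes exactly match the generator's
latent groups; all four clusters are stable (mean Jaccard ≥ 0.75 under
noise). The hazard ratios contrast each cluster against cluster 1 —
note cluster numbers are canonical (by decreasing size), so they need
not line up with the generator's subphenotype indices; the acceptance
script reports truth-matched hazard ratios instead.

A CLI mirrors the stages (`protraj simulate|preprocess|features|cluster|
stability|subsets|survival|run-all|compare-modes --config run.yaml
--seed N --outdir DIR`); results land as TSVs plus a JSON manifest
recording every seed, warning and file checksum.

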