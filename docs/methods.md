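# Methods

This note documents the statistical models behind `protraj`, the
choices made where the design was genuinely open, and what the bundled
synthetic cohorts do and do not establish about real data.

## Preprocessing

The aptamer panel is reduced deterministically: reagents with non-human
targets are removed, then reagents with non-validated targets, and when
several survivors bind the same protein only the reagent with the
smallest dissociation constant K_d is kept ("highest binding affinity"
is read as smallest K_d, the standard biochemistry convention). An
exact K_d tie is broken toward the lexicographically smallest reagent
id and recorded as a warning, so the filter is a pure function of the
annotation.

Per patient, the analysis samples are the baseline draw plus the last
two draws on or before the event/censoring time (their union, so a
patient contributes 1–3 samples). Retained RFU values are
natural-log-transformed and standardized per protein to Z-scores over
the *selected* samples, with the per-protein mean/SD stored for exact
inversion. The log base is immaterial downstream because features are
re-standardized again; natural log is used and recorded in the run
manifest. Zero-variance proteins are dropped with a manifest record. A
protein measured in relative fluorescence units carries no absolute
concentration meaning, which is why all modeling happens on the
standardized scale.

## Trajectory features

For each protein p the standardized values follow a linear mixed model

    y_ij = (β0 + b0_i) + (β1 + b1_i) t_ij + ε_ij,
    (b0_i, b1_i) ~ N(0, D),  ε_ij ~ N(0, σ²),

with time in years since baseline, so the intercept is the patient's
baseline level and the slope the yearly drift. Variance components are
estimated by profiled REML: D = σ²·LLᵀ with a log-Cholesky factor
(positive semi-definite by construction), σ² profiled out in closed
form, and the three free parameters optimized by Nelder–Mead with a
criterion tolerance of 1e-8 and at most 500 iterations. Because each
patient contributes 1–3 samples, every per-patient quantity reduces to
2×2 algebra through the Woodbury identity; BLUPs use the push-through
form (G⁻¹+XᵀX)⁻¹Xᵀr, which stays conditioned in the noiseless limit
where predictions approach each patient's own least-squares line.

REML rather than ML because variance components from 1–3 observations
per patient are otherwise noticeably biased. When the estimated
random-slope variance falls below 1e-10 the protein is refitted as
random-intercept-only and flagged; its slope feature is then the fixed
slope. Constant proteins yield a degenerate flagged fit.

The clustering features are the per-patient empirical BLUPs
(β0+b̂0_i, β1+b̂1_i). BLUPs are used rather than per-patient OLS
coefficients because most patients have too few samples for stable
individual fits; shrinkage toward the population line is exactly what
the mixed model is for. The n×2P block matrix [intercepts | slopes] is
re-standardized column-wise before embedding; without this the slope
columns, whose raw variance is an order of magnitude smaller, would be
invisible to Euclidean k-means. A consequence worth knowing: the
feature matrix is invariant to the upstream log base and to any affine
rescaling of single proteins.

Single-visit modes (baseline / second / last) skip the mixed models and
use the standardized values at the chosen visit, dropping (and
recording) patients who lack it.

## Consensus clustering

The feature matrix is embedded in 2 dimensions. UMAP
(n_neighbors = 15, min_dist = 0.1) is the default surface for
exploratory use; PCA and the identity are exact, deterministic
alternatives and the package's own large-scale runs use PCA — the
synthetic cohorts place the subphenotype means on two latent axes, so
the top two principal components already carry the full between-cluster
geometry, and an exact linear embedding keeps every downstream number
reproducible to the bit. Results at small scale with UMAP agree on the
selected k.

The cluster count is chosen by an ensemble vote: for every candidate k
in 2..8 the embedding is clustered by k-means (best of 25 k-means++
starts, Lloyd iterations with an asserted non-increasing objective) and
seven validity indices are evaluated — silhouette, Calinski–Harabasz,
Davies–Bouldin, Dunn, C-index, the gap statistic (20 uniform
bounding-box references, one-standard-error rule) and Hartigan
(smallest k with H(k) ≤ 10; if no k crosses the threshold the index
votes for its minimizer). Each index votes for its optimizing k; the
modal vote wins, ties toward smaller k. An index undefined on a
degenerate partition abstains. The seven indices were chosen to span
the compactness/separation families while remaining cheap enough to
verify against brute-force implementations; the full ~26-index
ensembles add mostly redundant votes.

The vote is run on 100 bootstrap resamples (patients drawn with
replacement, duplicates kept, each resample re-embedded), and the modal
winning k across resamples — together with its vote histogram — is the
consensus. The final k defaults to the modal k but is config-exposed,
because the choice among closely-voted candidates legitimately also
weighs stability and clinical interpretability.

Stability: each of R repeats adds i.i.d. N(0, τ²) noise (τ = 0.1) to
the standardized features, re-runs embedding and k-means at the final
k, and records per original cluster the best Jaccard overlap with any
perturbed cluster. Noise is injected in feature space, before the
embedding, so the whole pipeline is stress-tested. Mean Jaccard ≥ 0.75
flags a cluster as stable (the conventional cutoff). With τ = 0 and
reused seeds the procedure reproduces the original allocation exactly,
which the tests assert.

Cluster labels are canonicalized (numbered by decreasing size, ties by
smallest member id) so runs are comparable.

## Protein subsets and drivers

Proteins are clustered into subsets by k-means on the transposed
feature block (proteins as objects, patients as dimensions, Euclidean
distance), separately for intercepts and slopes, with k chosen by the
same seven-index vote in a single pass (no bootstrap). Subsets are
lettered A, B, C… by decreasing size.

Per protein, association with the subphenotypes is a tie-corrected
Kruskal–Wallis test on its per-patient feature values of that axis;
Benjamini–Hochberg correction is applied jointly across all proteins of
the axis (not within subsets), and a protein is called significant at
q ≤ 0.05 — the step-up rule, which is what reproduces the textbook
worked examples at the rejection boundary. The per-subset fraction of
significant proteins identifies driving subsets; top drivers are ranked
by ascending q then descending H.

Per-patient subset scores fit the one-way random-intercepts model
x_ip = μ + u_i + e_ip over the subset's proteins by profiled REML and
report μ + BLUP(u_i), the shrunken patient mean; when the
between-patient variance collapses to zero every score equals μ and the
collapse is flagged.

## Survival association

Clinical variables are compared across subphenotypes with
Kruskal–Wallis (numeric) or chi-square tests (categorical), switching
to Fisher's exact test when any expected cell is below 5 (2×2 exactly;
larger tables by seeded conditional Monte-Carlo with 10,000 draws).

Cox proportional-hazards models enter the subphenotype as dummies
against cluster 1 with four nested adjustment levels: (1) dummies only;
(2) + age, sex, eGFR; (3) + every clinical variable BH-significantly
associated with endpoint occurrence, with the age/sex/eGFR trio always
forced; (4) model 3 + NT-proBNP, entered log-transformed as is
conventional for a right-skewed biomarker. The partial likelihood uses
Efron tie handling (less biased than Breslow at moderate ties) and is
maximized by Newton–Raphson with step-halving, gradient tolerance 1e-9,
at most 100 iterations. A coefficient escaping |β| > 20 signals a
monotone likelihood and raises an error naming the covariate, as does a
singular information matrix. AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln(events).

Discrimination is Harrell's C over usable pairs (earlier time is an
observed event and the times differ; tied scores count ½), internally
validated by Harrell's optimism bootstrap with B = 200: refit on each
resample, optimism_b = C(boot model | boot data) − C(boot model |
original data), corrected C = apparent C − mean optimism. A resample
that empties a small subphenotype of events makes the refit separate;
such refits are stabilized with a light ridge penalty (λ = 0.1) rather
than discarded, the standard internal-validation practice — the run
errors out only if more than 10% of refits fail outright. Group
survival uses product-limit curves and the K-group log-rank test.

The repeated-vs-single-visit comparison runs both modes on the same
cohort and tabulates optimism-corrected C and BIC of the subphenotype
model (level 1 by default).

## The synthetic cohort

The generator emulates a serially-sampled chronic heart-failure
biomarker study: ~400 patients sampled at baseline and then trimonthly
(Gaussian scheduling jitter, SD 0.02 years ≈ 1 week, truncated to keep
times strictly increasing) until an event or censoring; an exponential
proportional-hazards endpoint with subphenotype-specific log hazard
ratios (defaults 0, ln 3.4, ln 2.9, ln 1.3, echoing the risk ordering
such cohorts report) and a baseline hazard of 0.07/year giving a ~30%
event rate; staggered-entry censoring uniform on [1.0, 2.7] years.
Mixing weights are proportional to reported subphenotype sizes
(90:121:128:43), so the smallest subphenotype genuinely has very few
events — which is exactly what makes the ridge stabilization above
necessary.

Protein structure: four subsets with sizes proportional to
1054:897:643:1615. The four subphenotype mean profiles sit on the
corners of a square in a two-dimensional latent space — subsets A and B
load their intercepts on one axis, subset D on the other, subset C
carries no signal, and slope effects follow the same two axes. The
`separation` parameter (default 1.5) scales contrasts so adjacent
subphenotypes differ by 1.5 within-subphenotype SDs per informative
protein. On top of the subset mean, each (patient, protein) pair draws
its own random intercept (SD 0.5) and slope (SD 0.25/year), plus
visit-level log-normal noise (SD 0.5); RFUs are emitted as
1000·exp(latent), so the log/Z-score path is exercised nontrivially.
Decoy aptamers (non-human, non-validated, duplicate-target at weaker
affinity, in the proportions a real panel's filter removes, about
5284→4210) exercise the annotation filter. Clinical covariates (age,
sex, eGFR, SBP, HF duration, NYHA class, atrial fibrillation, other
arrhythmia, chronic renal failure, diabetes, an NT-proBNP surrogate)
are drawn from subphenotype-shifted distributions.

What the generator does **not** emulate: inter-protein correlation
beyond shared subset means, missing-not-at-random sampling, competing
risks, assay batch effects, or the marginal distributions of any real
cohort. Passing tests therefore demonstrate that the machinery recovers
known structure under a faithful generative model of the study design —
not that a particular real dataset contains four subphenotypes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 400
patients × 500 structured proteins with 25 bootstrap resamples for
k-selection, 50 stability repeats and B = 200 optimism bootstrap — the
package's chosen desk-scale study conditions; every size is a config
parameter. Seeds: the pipeline derives per-stage seeds as
sha256(master_seed, stage) mod 2³¹, so no stochastic stage reuses
another's stream and a run is a pure function of (inputs, config).
Intermediate feature matrices are cached under the output directory
keyed by a config hash, so an interrupted run resumes without refitting
the mixed models.

Degenerate-input conventions: silhouette of a singleton cluster is 0
and of an all-identical dataset 0; Davies–Bouldin, Dunn, C-index and
Calinski–Harabasz abstain from the vote when their denominators vanish;
Jaccard(∅, ∅) = 1; Kruskal–Wallis on identical observations returns
H = 0, p = 1.

## Known limitations

* Trajectories are straight lines; no splines or joint
  longitudinal–survival models.
* The UMAP optimizer is library-backed and only reproducible per
  (version, seed); exact regression tests use the PCA/identity
  embeddings.
* The ADAT reader supports a minimal dialect (section sentinels, one
  metadata block each for aptamers and samples) sufficient for fixtures
  and simple exports, not the full vendor format.
* Pathway/enrichment annotation of protein subsets requires external
  databases and is out of scope.
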