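# Methods

This note documents the models, estimators and numerical choices in
fcpipe, what the synthetic-cohort generator does and does not emulate,
and the design decisions taken where the analysis family leaves details
open.

## Static connectome construction

Per subject, the N×N Pearson correlation matrix of parcel time series is
computed on the full (assumed pre-denoised) series, with no detrending
and no Fisher z-transform; the diagonal is stored as 0 and excluded from
all edge statistics. Negative correlations are suppressed to zero before
thresholding. Sparsity thresholding is proportional with a connectedness
guarantee:

1. **Backbone.** A maximum spanning tree over the positive correlations
   — Kruskal's algorithm on weights `r`, which for any strictly
   decreasing weight transform (`1 − r`, `1/r`) is the same tree as a
   minimum spanning tree on the transformed weights. Ties are broken
   lexicographically on (min index, max index), making results
   bit-reproducible. If negative suppression disconnects the graph (it
   never does for realistic FC data) the backbone is built from the raw
   pre-suppression weights, and any non-positive backbone weights are
   retained as-is with a logged warning.
2. **Densification.** Remaining positive edges are added in descending
   weight order (same tie-break) until `K = round(s·N(N−1)/2)` edges are
   retained; `s = 0.10` by default, so a 400-parcel network keeps a
   399-edge backbone and 7980 edges total. Retained edges keep their
   original correlation values; thresholding never alters a weight.

Requesting a sparsity below spanning-tree density (`K < N−1`), or more
edges than positive correlations exist, is an error that reports the
achievable sparsity. An ablation switch (`use_mst_backbone=False`)
selects plain top-K edges without the connectedness guarantee.

## Graph topology

* **Mean FC** — arithmetic mean of the K retained weights.
* **Global efficiency** — `E = (1/(N(N−1))) Σ_{i≠j} 1/d(i,j)` with
  weighted shortest-path distances using edge length `1/w`, the Brain
  Connectivity Toolbox convention for weighted efficiency. Computed by
  Dijkstra on the sparse retained graph; disconnected input is an error.
* **Modularity** — Newman's spectral method: repeated bisection by the
  leading eigenvector of the (generalized) modularity matrix, each split
  refined by Kernighan–Lin-style single-node sweeps (each pass moves
  every node once, keeps the best prefix, and repeats while it improves;
  gains below cancellation noise, `1e-9·N·max|B|`, count as ties so the
  refinement terminates on flat landscapes). A split is accepted only if
  it increases Q. The reported Q uses the standard weighted formula
  `Q = Σ_m (e_mm − a_m²)` at resolution 1. Metrics are computed on the
  weighted thresholded network by default, with a binary option.
* **Eigenvector centrality** — power iteration on `A + I` (the identity
  shift preserves the Perron vector and guarantees convergence on
  bipartite-like graphs), relative tolerance 1e-10, sign-fixed
  nonnegative, normalized to unit Euclidean norm. At N = 400 this puts
  typical values on the ~1/√400 ≈ 0.05 scale.
* **Wiring distance** — "anatomical distance" is Euclidean distance
  between MNI centroids. Bins: short ≤ 45 mm, 45 mm < middle < 75 mm,
  long ≥ 75 mm; both boundary values follow those conventions exactly.

## Network-based statistic

Edgewise pooled-variance two-sample t-tests (df = n_a + n_b − 2) on the
raw unthresholded correlations; edges with zero pooled variance get
t = 0, p = 1. Covariates are not regressed out at this stage (a
residualize-first helper exists for sensitivity analyses). Suprathreshold
edges (two-sided p below the primary threshold, default 1e-4) are split
by sign into separate "increased" and "decreased" analyses, each with
its own null distribution of maximal component sizes over random
relabelings of the pooled subjects. The randomized permutation p uses
the +1/+1 correction; an exhaustive mode enumerates all distinct splits
for tiny groups. Components with adjusted p below α (default 0.01) are
significant; inference is valid only at the component level. The null
permutation stream is generated in a content-canonical subject order, so
p-values are invariant to how subjects happen to be ordered within
groups. If the observed data yield no suprathreshold component at all,
no permutations are spent.

## Dynamic stability

Rectangular (untapered) sliding windows, default length 62 TR and step
2 TR — 120 windows for a 300-volume run; windowed matrices keep raw
correlations (no suppression, no sparsification). Cortical stability of
parcel *i* is the intraclass correlation of its (N−1)×W profile of
connections across windows. The estimator is the one-way random-effects
ICC(1,1) = (BMS − WMS)/(BMS + (W−1)·WMS) with edges as targets and
windows as measurements — the minimal-assumption form, since windows are
not meaningful "raters" with their own systematic effects; ICC(2,1) is
available by configuration. Negative estimates are reported as computed
(not clamped) so downstream group statistics stay unbiased; a globally
constant profile returns 0 with a warning.

## Group statistics

* Kruskal–Wallis (tie-corrected, chi-square p) for continuous
  demographics and scores; pairwise post-hocs are Mann–Whitney tests
  with BH correction (the pairwise non-parametric choice left open by
  the workflow).
* Pearson chi-square (no continuity correction) for categorical tables.
* ANCOVA: OLS of the response on group dummies plus covariates (age,
  sex coded 0/1, optionally mean FD under the sensitivity flag); the
  group F compares against the covariates-only model. Post-hoc p-values
  are unadjusted pairwise contrast t-tests inside the full model.
  Cohen's d is computed on covariate-residualized responses with the
  pooled-sd formula, so the effect size matches the adjusted contrast.
  A constant response returns F = 0, p = 1, d = 0.
* Partial correlation: residualize both variables on the covariates
  (with intercept), correlate the residuals, p from t with
  df = n − 2 − c.
* FDR: Benjamini–Hochberg step-up; families follow the analysis
  structure (e.g. all 400 nodal centrality tests form one family; the
  clinical correlations of one network parameter form one family).

## Classification

The subnetwork connectivity index is the mean raw correlation over an
NBS component's edges. Discrimination uses stratified k-fold (default 5)
cross-validated unregularized logistic regression on that single index;
stratification avoids degenerate single-class folds at cohort sizes
around 148. Accuracy is pooled over held-out predictions at the 0.5
cutoff; AUC is computed from pooled out-of-fold probabilities, with
per-fold AUCs also reported. **Caveat:** when the component is selected
on the same subjects that are cross-validated (as in the reproduced
workflow), selection leaks group information and the accuracy/AUC are
optimistically biased; treat them as descriptive, not as out-of-sample
estimates.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis
consumes, not BOLD physiology:

* **Atlas** — contiguous network blocks of near-equal size; network
  centers on a 55 mm lattice with per-parcel isotropic jitter (sd 8 mm),
  so within-network pairs are short-range and between-network pairs span
  the middle and long bins (guaranteed for ≥ 3 networks).
* **Covariance** — unit-diagonal block-modular matrices: within-network
  r = 0.35, between-network r = 0.08 by default, plus a group-specific
  global offset (default +0.04 for the UC-like group, its "higher global
  FC"). The planted subnetwork is a clique over 10 nodes spanning two
  networks with edges raised by Δr (default 0.12); a clique bump
  `δ(J − I)` has minimum eigenvalue −δ, so moderate deltas stay PSD
  without projection. Any non-PSD construction is projected to the
  nearest correlation matrix (eigenvalue clipping + re-normalization)
  with a logged warning, never silently.
* **Time series** — zero-mean Gaussian draws (white in time; the
  analysis consumes only second-order structure, so hemodynamic
  convolution and band-pass filtering are deliberately absent; an AR(1)
  option was considered and left out as it would not change any
  correlation-based estimand). Each group has two covariance states —
  the base matrix and a parcel-permuted configuration (blend weight
  `state_contrast`, default 1.0, i.e. two genuinely different modular
  configurations, the abstraction used in dynamic-FC state modelling).
  The active state switches with probability 1/dwell per sample
  (geometric dwell, uniform jump). The per-subject stability parameter
  s ∈ [0, 1] maps log-linearly to dwell ∈ [20, 5000] samples: stable
  subjects rarely switch, so their windowed connectivity profiles are
  consistent and their ICC is high. Group stability means default to
  HC 0.38 < IBS 0.50 < UC 0.64, producing the HC < IBS < UC cortical
  stability ordering. The planted clique is applied to *both* states
  (a trait effect, not state-dependent).
* **Phenotypes** — age/sex/motion draws are made once per within-group
  index and copied across groups, so groups are matched by construction.
  Clinical scores are `intercept + slope·s + noise` per configured
  loading (SF-12 mental component loads negatively); default slopes give
  within-group stability–score correlations in the r ≈ 0.3 range typical
  of questionnaire–brain associations. Disease duration (UC-like group
  only) is independent of everything, matching the reported absence of
  duration effects.

What passing tests on this generator do **not** show: robustness to
scanner/site effects, motion artifacts, physiological noise, temporal
autocorrelation, or subject-level variation in covariance structure
beyond the state mixture — all real-data features the generator omits.
With long-dwell subjects the realized state occupancy is close to
binary, which inflates within-group heterogeneity of static matrices for
high-stability groups; this is a designed feature of the state model,
flagged here because it strengthens apparent global group differences
at large n.

## Calibration and recovery studies

The test and acceptance suites run the pipeline at reduced problem sizes
chosen to finish on one CPU while keeping each check informative:

* **NBS family-wise error** — 100 null cohorts (2 × 12 subjects, 15
  parcels, T = 100) × 500 permutations at α = 0.05. The edge-level
  threshold for this calibration is p < 0.01: at these sample sizes the
  pipeline's primary 1e-4 threshold almost never yields any
  suprathreshold edge under the null, which would make the FWER estimate
  vacuously 0; NBS controls FWER at any primary threshold, so the
  calibration uses one that actually exercises the component null.
* **ANCOVA type-I error** — 200 null simulations (3 × 30, two
  covariates) at α = 0.05.
* **Null classifier AUC** — 50 label-independent indices at n = 148.
* **Recovery** — a stationary two-group cohort (30 + 30 subjects, 60
  parcels, Δr = 0.15 on a 45-edge planted clique) for NBS Jaccard and
  index AUC; a wide-stability cohort (n = 30, T = 600, stability sd
  0.35) for the ICC–stability-parameter correlation, where T = 600 keeps
  the realized number of state switches informative about the dwell
  parameter; and an n = 74 cohort with a strong score loading (slope 20,
  noise sd 2) for the stability–symptom partial correlation. The
  effect-size recovery check for ANCOVA asserts the *mean* |d| across 20
  replicates lies in [0.7, 1.3]: a per-replicate band of that width is
  narrower than the sampling noise of d at n = 74/group (sd ≈ 0.17) and
  would fail by chance.
* **Full-scale smoke** — the default 222-subject, 400-parcel cohort runs
  the complete workflow with permutations reduced to 200; it asserts
  every network is connected with exactly 7980 edges and a 399-edge
  backbone.

## Known limitations

* The generator's uniform global offset makes most edges differ between
  the offset group and controls at n = 74, so full-scale NBS components
  are much larger than those reported for real cohorts; effect
  magnitudes are illustrative, not calibrated to empirical effect sizes.
* ICC estimates treat edges as independent targets; spatially correlated
  edges violate the one-way ANOVA independence assumption, as they do in
  any windowed-ICC analysis of connectomes.
* The CV evaluation of the subnetwork index reproduces the selection
  circularity of the original workflow (see Classification above).
* Wiring-distance proportions on synthetic atlases are dominated by
  short-range (within-network) edges because strong correlations
  concentrate within spatially compact networks; group contrasts of the
  proportions remain meaningful, absolute values are atlas-dependent.
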