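# Methods

## The model

`petmpi` treats a patient's whole-body PET presentation as a point in a
20-dimensional feature space and assumes the cohort lies near a
one-dimensional manifold parameterized by disease severity. The
Metabolic Progression Index is the rank position of each patient along
the dominant axis of that manifold.

**Feature extraction.** Lesions are voxels with SUV strictly above 2.5
(the fixed clinical threshold), grouped into 26-connected components;
world coordinates are voxel centres (origin + index × spacing), volumes
are voxel count × voxel volume. Per lesion we record MTV, SUVmean,
SUVmax, TLG = MTV × SUVmean, summed SUV, and the unweighted centroid.
The 20 patient-level features comprise four families: global burden
(tMTV, tTLG, Intensity_Sum, MeanIntensity_Sum, Volume_intensity_sum),
dominant-lesion descriptors (MTV_Bulk, MTV_Smallest, tSUVmax,
MaxIntensity_Min), inter-lesional heterogeneity (pairwise and
bulk-anchored difference sums over volumes and SUVmax), and spatial
dissemination (DmaxVox over pooled voxels, and centroid-based Dmax,
BulkDmax, BulkCentroidCoor_DistMax, SmallestCentroidCoor_DistMax).
Conventions worth stating:

* the bulk lesion is the largest-MTV lesion; ties break to the higher
  summed SUV, then the lower lesion id, so output is deterministic;
* Bulk_Volume_DiffSum uses signed (bulk − other) differences, which are
  non-negative by construction; the intensity analogue uses absolute
  differences because the bulk lesion need not carry the peak SUVmax;
* Volume_intensity_sum is Σᵢ MTVᵢ × (summed SUV)ᵢ — the reading whose
  magnitude matches published cohort tables;
* DmaxVox pools voxels within and across lesions, so a single-lesion
  patient gets its maximal chord; it is computed exactly (chunked
  brute force), never approximated;
* BulkDmax and BulkCentroidCoor_DistMax are the same centroid-wise
  quantity under the definitions used here; both columns are kept so
  the matrix always has the canonical 20 names;
* Σ|pairwise differences| is evaluated by the sorted-prefix identity
  Σₖ(2k − n − 1)·v₍ₖ₎, O(n log n), verified against the O(n²) form.

**Embedding.** Features are z-scored per column (population SD;
constant columns dropped with a warning). The diffusion operator uses a
Euclidean kNN graph (k = 20, union symmetrization — mutual kNN
disconnects small cohorts), a locally adaptive Gaussian kernel
W_ij = exp(−d²ij/(σᵢ² + σⱼ²)) with σᵢ = half the distance to the k-th
neighbour, anisotropic normalization with α = 1 (divides out sampling
density), and row normalization to a Markov operator. A bandwidth sweep
(σᵢ = d_k, 2d_k) measurably *worsened* ordering stability across k, so
the d_k/2 scale is kept. Eigenvectors come from the symmetric conjugate
D^{1/2}PD^{−1/2} via a dense symmetric solver — exact, deterministic,
and cheap at cohort sizes (n ≲ 10³); the trivial eigenpair (λ = 1,
constant vector) is excluded and a fixed sign convention is applied.
A disconnected graph is a hard error by default ("largest component" is
an explicit override), because a single ordering across disconnected
components is meaningless.

**MPI.** DC1 is defined up to sign, so it is oriented by its Spearman
correlation with tMTV (fallback DmaxVox if |ρ| < 0.05; error if both are
ambiguous); low DC1 then means low burden. The root is the patient with
the lowest oriented DC1. MPI = (rank − 1)/(n − 1) with average ranks on
ties: rescaling ranks rather than raw DC1 values makes MPI invariant to
any strictly increasing transform of DC1 (the raw min–max variant is
available as `method="raw"` and correlates > 0.99 with the rank form on
well-structured cohorts). The alternative root rule (`min_tmtv`)
anchors orientation on the minimal-tMTV patient instead.

**Robustness suite.** Four analyses, each rerunning the *entire*
derivation under a perturbation and scoring Spearman agreement:
80%-subsampling (300 iterations, re-standardized within each subsample —
the stricter choice; frozen scaling is a flag), a k = 10..30 sweep
against k = 20, ablation of {Dmax, DmaxVox}, and the minimal-tMTV root.
Per-iteration values are stored, and everything is bitwise reproducible
under a fixed seed.

**Prognostics.** Univariable screening uses Mann–Whitney p-values and
AUC = U/(n₁n₀) with DeLong confidence intervals. The two predefined
logistic models are MPI + bone metastasis and tMTV + DmaxVox + bone
metastasis (maximum likelihood, Wald intervals); effects of 0–1-scaled
covariates are additionally reported per 0.1-unit increase as
exp(0.1β). Correlated ROC curves are compared with the paired DeLong
test (structural components; identical prediction vectors return p = 1,
and a degenerate variance — e.g. two perfect but different markers — is
an explicit error rather than p = 0). Nested models are compared by the
likelihood-ratio test on deviances. Internal validation is Harrell's
bootstrap optimism correction (resampling stratified on outcome so both
classes stay present at n ≈ 83 with ~72% events). Calibration is
decile-grouped observed vs mean predicted risk. Survival uses
Kaplan–Meier with log-log (exponential Greenwood) intervals and Cox
proportional hazards with Efron ties and Harrell's C-index (via
lifelines), VIFs are 1/(1 − R²) from per-covariate OLS, and the
nonlinear comparator is a logistic model in z-scored tMTV and DmaxVox
plus their squares. One definitional note: the per-0.1 hazard ratio is
always exp(0.1β) computed from the fitted 0–1-scale coefficient; a
published per-0.1 value that is inconsistent with its own 0–1-scale
hazard ratio cannot be matched by any coefficient and is not a target.

## The synthetic cohort generator

The generator is the package's study population, not a test fixture.
Each patient draws severity s ~ U(0, 1), which drives, with
*partially independent* noise channels:

| quantity | model | default |
| --- | --- | --- |
| extra lesions | 1 + Poisson(base + slope·s) | (0.5, 14) |
| bulk volume (ml) | LogNormal(log base + slope·s, sd) | (log 100, 1.2, 0.35) |
| met volume (ml) | LogNormal(log base + slope·s, sd) | (log 0.25, 1.0, 0.7) |
| peak SUVmax | LogNormal(log 15, 0.15), independent of s | — |
| met SUVmax | peak × U(0.35, 1) | — |
| dispersion radius (mm) | (30 + 220·s)·LogNormal(0, 0.5) | — |
| 12-mo death | Bernoulli(expit(−2.7 + 10·s)) | marginal 72.4% |
| OS (months) | Weibull(1.2, 14.5) PH with log-HR 1.5·s | median ≈ 6.2 |
| bone metastasis | Bernoulli(expit(−0.6 + 1.5·s)) | prevalence ≈ 54% |

Geometry: the bulk lesion sits in the chest-like upper half of a body
cylinder (radius 150 mm, height 1000 mm); metastases are placed
uniformly in a ball of the dispersion radius around it, rejected until
they are inside the body and clear every placed sphere by more than a
voxel diagonal (so rasterized lesions stay separate 26-connected
components), with a deterministic cylinder-grid fallback for crowded
configurations. Consistency of the outcome pair is guaranteed by
construction: the 12-month death flag is drawn from the logistic link
first and the Weibull survival time is then drawn *conditionally*
truncated to (0, 12] or (12, ∞), with administrative censoring at 36
months.

Design rationale for the defaults, which were calibrated once against
the package's own invariant battery and then frozen:

* **Peak SUVmax is a patient-level draw** carried by the bulk lesion.
  Drawing per-lesion SUVmax i.i.d. would make tSUVmax — the maximum
  over a severity-dependent lesion count — correlate ≈ 0.3 with
  severity, contradicting the intended null; with the patient-level
  peak, Spearman(s, tSUVmax) ≈ 0.
* **No single feature is a clean severity readout.** Lesion count is
  the strongest channel (expressed through the heterogeneity and
  intensity-sum features), bulk volume and dispersion are moderate and
  carry their own patient-level noise; measured couplings at n = 500
  are ρ(s, tMTV) ≈ 0.6, ρ(s, DmaxVox) ≈ 0.75, ρ(s, Volume_DiffSum)
  ≈ 0.8, while the manifold-integrated MPI reaches ≈ 0.88. A wide
  peak-SUV spread was specifically avoided because several features
  share that one draw, and a coherent severity-null block attracts DC1.
* **The outcome link is steep** (slope 10 on the 0–1 severity scale,
  intercept set so the analytic mortality integral stays at 72.4%).
  This is the regime the fitted effect sizes of rank-scaled indices
  imply once attenuation from an imperfect severity proxy is undone,
  and it is what lets a better severity estimate show up as a higher
  AUC.

**Two fidelities.** The fast path computes all 20 features in closed
form from sphere geometry (SUVmean of the linear radial profile is
0.25·SUVmax + 0.75·threshold; DmaxVox ≈ max over pairs of
centre distance + both radii, including the within-lesion chord 2r).
The slow path rasterizes spheres onto a 4 mm grid with SUV decaying
linearly from SUVmax at the centre to just above 2.5 at the boundary
(centre voxel set to SUVmax exactly, background uniform well below
threshold) and runs real segmentation. Distances agree within one voxel
diagonal; per-lesion MTVs agree within max(one voxel, 1.5%) — the
lattice-point error of a sphere scales with its surface area, so a
fixed one-voxel equivalence is attainable only for small lesions.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: respiratory motion, partial-volume
effects, scanner and reconstruction noise, physiological uptake,
non-spherical lesion shapes, organ-constrained metastatic topography,
and any treatment effect on survival. Passing the battery shows the
*pipeline* recovers a latent ordering and reproduces method-level
stability under the stated cohort structure; it does not validate
cohort-specific published effect sizes, which require the original
patient data.

## Numerical choices and degenerate inputs

* Segmentation is strictly above threshold; an image with no
  supra-threshold voxel yields an explicit "no disease" lesion set, and
  downstream feature computation refuses it.
* Duplicated patients receive numerically identical embedding
  coordinates; the rank transform then splits the exact tie
  arbitrarily, so orderings agree up to adjacent-rank swaps.
* σᵢ is floored at 1e−12 (duplicate-heavy inputs); eigen-decomposition
  validates the trivial eigenpair (λ₁ = 1, constant eigenvector) and
  fails loudly otherwise.
* Logistic fits flag (quasi-)separation by diverged coefficients
  (|β| > 30) and name the culprit covariate; bootstrap optimism
  tolerates up to 5% failed resample fits.
* Exact collinearity in VIF returns infinity for the involved
  covariates rather than a numeric explosion.
* All stochastic stages (generator, subsampling, bootstrap) take
  explicit seeds; the pipeline derives stage seeds from one master seed
  with fixed offsets.

## Problem sizes

The default analyses run on n = 83 cohorts: the full robustness suite
(300 subsample embeddings + 21 k-settings) takes a few seconds, the
1000-iteration bootstrap under a minute, and the 50-cohort model
comparison about two minutes. These sizes are the study conditions the
package models; nothing in the implementation caps n, and the dense
eigensolver remains practical to a few thousand patients.

## Known limitations

* MPI is a single-axis summary; branching disease trajectories and
  higher diffusion components are out of scope by design.
* The min-tMTV root rule orients by which half of the ordering contains
  the root; when burden noise places the minimal-tMTV patient near the
  middle of the trajectory, the rule is genuinely ambiguous and its
  concordance with the default rule degrades.
* The k-sweep concordance minimum fluctuates ≈ 0.993–0.998 across
  generator seeds: a single real cohort reports one draw from that
  distribution, and simulated cohorts match it in distribution, not at
  every seed.
* In-sample AUC comparisons between models of different dimensionality
  carry unequal optimism; the package reports Harrell-corrected AUCs
  alongside apparent ones, and the cross-seed comparison script shows
  both.
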