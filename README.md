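# petmpi

A pseudotime **Metabolic Progression Index (MPI)** from whole-body
¹⁸F-FDG PET, for prognostic stratification of extensive-stage small cell
lung cancer — implemented end to end on synthetic cohorts with a known
latent severity axis.

Conventional PET biomarkers — total metabolic tumor volume (tMTV), total
lesion glycolysis (tTLG), and dissemination distances such as DmaxVox —
are strongly collinear readouts of a single underlying process: systemic
disease progression. Rather than picking among them, `petmpi` embeds a
20-feature description of each patient's lesion set (burden,
dominant-lesion, inter-lesional heterogeneity and spatial dissemination
families) into a diffusion map, interprets the first diffusion component
DC1 as the latent severity axis, and rank-rescales it into MPI ∈ [0, 1].

The core construction, for a z-scored feature matrix **X** (n patients ×
20 features):

1. k-nearest-neighbour graph (Euclidean, k = 20, union symmetrization),
   local kernel scale σᵢ = ½·(distance to the k-th neighbour);
2. affinities W_ij = exp(−d²_ij / (σᵢ² + σⱼ²)), anisotropic α = 1
   normalization W̃ = W / (q qᵀ) with q the row sums, then the Markov
   operator P = D⁻¹W̃;
3. spectral decomposition through the symmetric conjugate
   S = D^{1/2} P D^{−1/2}; DC1 is the right eigenvector of the largest
   non-trivial eigenvalue;
4. DC1 is sign-oriented against tumor burden (Spearman with tMTV), the
   root is the patient with the lowest oriented DC1, and
   MPI = (rank(DC1) − 1)/(n − 1).

Because no patient-level data accompany the study design this package
follows, a first-class synthetic-cohort generator
(`petmpi.synthetic`) produces stage-IV-like cohorts (n = 83, ~72%
12-month mortality, median OS ≈ 6 months, multi-lesion disease) in which
every feature family is a *noisy* readout of one latent severity
s ~ U(0,1) while peak SUVmax carries no severity signal. Lesions exist
both as closed-form sphere geometry (fast path) and as rasterized SUV
images segmentable at the fixed 2.5 threshold (slow path), so the entire
chain — segmentation → features → embedding → MPI → robustness →
prognostics — is testable against ground truth.

## Worked example

```python
from petmpi import GeneratorParams, sample_cohort, cohort_feature_matrix, derive_mpi
from petmpi.synthetic import outcomes_frame
from scipy.stats import spearmanr

params = GeneratorParams(n_patients=83, seed=0)
cohort = sample_cohort(params)
fm = cohort_feature_matrix(cohort, params)      # 83 x 20 feature matrix
res = derive_mpi(fm, k=20)
truth = outcomes_frame(cohort)
print(round(spearmanr(res.mpi, truth.severity)[0], 3))
print(res.root_patient_id, round(fm.loc[res.root_patient_id, "tMTV"], 0))
```

prints

```
0.857
P16 131.0
```

— the recovered MPI ordering correlates 0.86 with the generator's hidden
severity, and the trajectory root is a mild patient (131 ml tMTV against
a cohort median of 199 ml). The numbered scripts under `analysis/`
continue the narrative: `03_stability.py` reproduces the ordering's
robustness (median |ρ| = 0.998 across 300 80% subsamples, min |ρ| = 0.998
across k = 10..30, ρ = 0.997 after dropping both dissemination features,
ρ = 1.000 under a minimal-tMTV root), and `04_prognostics.py` fits the
predefined 12-month-mortality models (MPI + bone metastasis vs
tMTV + DmaxVox + bone metastasis), the DeLong ROC comparison,
likelihood-ratio testing, bootstrap optimism correction, calibration,
Kaplan–Meier and Cox analyses.

A `petmpi` command-line interface mirrors the same stages
(`petmpi simulate`, `extract`, `embed`, `mpi`, `robustness`,
`prognostics`, `run-all`) for CSV/NIfTI inputs.

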