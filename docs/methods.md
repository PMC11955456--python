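# Methods

`habitatrx` implements a habitat-based radiomics analysis for biparametric
prostate MRI (axial T2-weighted imaging plus the ADC map), built to
distinguish clinically significant prostate cancer (csPCa, Gleason ≥ 3+4)
from non-significant disease (Gleason 3+3).  Three models are constructed
and compared: a clinical model (screened PSA-type covariates), a
whole-lesion radiomics model, and a habitat model built from per-subregion
radiomics.  Because no patient cohort is distributed with the package, a
synthetic phantom generator with known ground truth provides the study
conditions for every test and experiment.

## Pipeline

1. **Preprocessing.** Volumes are corrected for low-frequency intensity
   bias and resampled to isotropic 1 mm spacing (trilinear for images,
   nearest-neighbour for masks).  The bias corrector fits a polynomial of
   total degree 3 to the log-intensities inside the gland, divides by the
   exponentiated field and rescales to preserve the masked mean.  A full
   N4-style corrector can be substituted through the `corrector=` hook; the
   polynomial model is deliberately simple because preprocessing is a fixed
   step here, not a contribution.  Registration is out of scope: inputs
   must be co-registered (phantoms are aligned by construction).
   Output dimensions follow `round(dim * spacing / target)` with the world
   convention `position = index * spacing` (no direction matrix).

2. **Voxel feature maps.** Every lesion voxel receives a 42-dimensional
   feature vector: per modality, 10 first-order statistics (mean, variance,
   SD, skewness, excess kurtosis, energy as the mean of squares, binned
   entropy, min, max, range) and 10 grey-level co-occurrence (GLCM)
   statistics (contrast, correlation, joint energy, joint entropy, inverse
   difference moment, difference average, cluster shade, cluster
   prominence, maximum probability, autocorrelation) over a cubic window of
   side `2 * kernel_radius + 1` intersected with the lesion mask, plus the
   two raw intensities.  Defaults: kernel radius 2 (a 5 mm window at 1 mm
   spacing) and 16 equal-width grey levels over the *lesion-wide* range, so
   neighbouring windows share a level scale and the features are invariant
   to increasing affine intensity maps (a general monotone map would
   redistribute voxels across equal-width bins, so full monotone invariance
   does not hold and is not claimed).  Window energy is normalised by the
   window voxel count; an unnormalised sum would encode the window
   truncation at the lesion boundary rather than tissue texture, and that
   nuisance axis would dominate the standardised feature space.
   Co-occurrences are symmetric, distance 1, pooled ("merged") over the 13
   unique 3-D directions; a 2-D (axial, 4-direction) mode is available via
   config.  Windows with no valid voxel pair are flagged and take the GLCM
   values of the nearest valid voxel.

3. **Habitat clustering.** Voxel vectors pooled over training-set lesions
   are z-scored (constant columns pinned to 0 and flagged) and clustered
   with K-means (k-means++, Lloyd, 10 restarts, tolerance 1e-6).  The
   number of habitats is the argmax of the Calinski–Harabasz index
   CH(K) = [B/(K−1)] / [W/(N−K)] over candidates K = 2..9 (ties to the
   smaller K; +inf when W = 0).  A seeded uniform subsample (default cap
   100,000 voxels) keeps the scan tractable.  The fitted model is applied
   to every lesion, training and held-out alike, so habitat identities are
   cohort-consistent; fitting per lesion would make "habitat 2" mean
   different things in different patients.  Cluster indices are relabelled
   by ascending centroid raw-ADC, making habitat 1 the lowest-ADC (highest
   cellularity proxy) subregion in every run.

4. **Region radiomics.** For the whole lesion and for each habitat
   subregion, on both modalities: first-order (14 statistics), GLCM (10),
   grey-level run-length (8), size-zone (7), dependence (7) and
   neighbourhood grey-tone difference (5) families, plus modality-independent
   3-D shape (9) and 2-D shape on the largest axial slice (6).  These are
   native implementations of the standard IBSI-style definitions with a
   documented subset per family; NGTDM canonically defines exactly five
   statistics, so that family carries five.  Discretisation is fixed bin
   count (default 32) over the region's own range; run/co-occurrence
   matrices are merged over the 13 directions; zones and dependence
   neighbourhoods are 26-connected.  NGTDM coarseness is capped at 1e6 for
   constant regions.  An `extractor=` hook lets a full external IBSI
   extractor replace the native one.  Habitat regions a patient lacks (or
   below the 5-voxel floor) are recorded with a reason and imputed with the
   training-set column median.

5. **Feature selection.** Four stages fitted on training rows only, each
   nested in the previous: (i) mutual-information filter — plug-in MI with
   10 equal-frequency bins, keep `min(300, ceil(p/2))` columns; (ii) greedy
   mRMR to 30 features, criterion `I(f; y) − mean_{s∈S} I(f; s)` with the
   same plug-in estimator on a 10×10 quantile grid; (iii) squared-loss
   LASSO on the 0/1 label, λ on a 100-point log grid from λ_max down four
   decades, chosen by minimum 10-fold stratified CV-MSE (the squared-error
   criterion is the stated selection rule; a logistic-deviance mode exists
   in config), keeping coefficients with |β| > 1e-10; (iv) greedy Pearson
   pruning at |r| > 0.8 in order of descending |LASSO coefficient|.  Ties
   break by feature name everywhere, so the cascade is deterministic.

6. **Models.** Clinical: per-factor (univariable) logistic regression over
   age, PV, tPSA, fPSA, f/t ratio and PSAD, keeping Wald p < 0.05; under
   complete separation the Wald statistic degenerates (Hauck–Donner), so a
   small-ridge Newton refit supplies the p-value.  All three models are
   then fitted with a learner from an eleven-entry registry (logistic and
   linear regression, KNN, decision tree, SVM, XGBoost, random forest,
   LightGBM, MLP, gradient boosting, AdaBoost); random forest (500 trees,
   √p features per split, class-balanced weights) is the constructed
   default, the others are retained for learner screening.  The decision
   threshold is the training-set Youden-J maximiser (ties to the lowest
   cut).

7. **Evaluation.** AUC is the normalised Mann–Whitney statistic (ties
   half); its CI and paired model comparisons use DeLong's placement-value
   covariance with a normal approximation.  Confusion metrics are reported
   at the Youden threshold.  Calibration uses equal-frequency bins (default
   10).  Decision curves report NB(t) = TP/N − (FP/N)·t/(1−t) on t ∈
   (0, 1) against treat-all and treat-none.  Repeated cross-validation
   (default 5 repeats × 4 stratified folds) re-runs the *entire* per-model
   pipeline inside each training fold — selection cascade, clinical screen,
   and for the habitat model the K-means refit on the fold's training
   voxels — so CV estimates are leakage-free; whether the original analysis
   refit selection per fold is not documented, and this stricter choice can
   only make our CV estimates conservative.

## Synthetic study conditions

Clinical covariates are drawn class-conditionally: lognormal for the
PSA-type variables and prostate volume (their published median/(Q1,Q3)
summaries are right-skewed), truncated normal on [45, 95] for age.  A
lognormal is calibrated to a median/(Q1,Q3) summary by `mu = ln(median)`
and the least-squares `sigma = ln(q3/q1) / (2 * z75)`.  PV is factored
into width/length/height with lognormal anisotropy jitter so the ellipsoid
identity PV = W·L·H·0.52 holds exactly; PSAD = tPSA/PV and the free/total
ratio are always computed from the identities, never drawn.  Defaults
reproduce the 134:41 class imbalance.  The PV and f/t rows of the published
*total* column appear to duplicate other rows (transcription artefacts), so
generators calibrate to the class-conditional columns only.

Each phantom is an ellipsoidal gland (T2 ≈ 420, ADC ≈ 1600) containing an
ellipsoidal lesion of roughly 2,300–6,200 voxels at the native
64×64×32 grid with 1×1×3 mm spacing (typical axial prostate acquisition;
the anisotropy exercises the resampling stage).  The lesion is partitioned
into K_true = 3 spatially contiguous subregions by quota-constrained
multi-seed region growing (priority = distance to the habitat's seed plus a
smoothed-noise term), with quotas drawn from a Dirichlet around the class
mixture — csPCa (0.2, 0.3, 0.5) vs non-csPCa (0.5, 0.3, 0.2) over habitats
ordered by ascending ADC, concentration 10 (wide between-patient
compositional variability, as real lesions show).  The three habitats model
distinct tissue phenotypes:

| habitat | phenotype | ADC mean | T2 mean | texture |
|---|---|---|---|---|
| 1 | densely cellular | 800 | 400 | fine-grained, high variance (130², corr 0.7) |
| 2 | stromal/fibrotic | 1100 | 270 | smooth (35², corr 2.5) |
| 3 | necrotic/cystic | 1400 | 490 | coarse, bright (85², corr 1.3) |

so habitats differ in *texture* (grain and dispersion) as well as mean
signal — the premise of texture-based habitat imaging.  Habitat fields are
stationary Gaussian random fields blended across a ~0.8-voxel transition
zone (abundance-weighted mixing), then the volume receives a 0.4-voxel
point-spread blur, a multiplicative low-order polynomial bias field
(amplitude 0.2), and white noise at 5% of the habitat-mean range.  The
class additionally shifts the cellular habitat's ADC by ∓40 (csPCa lower):
denser cellularity in aggressive disease.  This is deliberately a
*subregional* signal — whole-lesion aggregates dilute it across the
mixture, which is what gives the habitat model its edge over whole-lesion
radiomics here.  Per-patient scanner-gain jitter knobs exist but default to
0 because the pipeline applies no per-patient intensity normalisation.

Master seed `s` spawns per-patient streams as `SeedSequence(s, spawn_key=(1, i))`
and the clinical table as `spawn_key=(0,)`; the rule is recorded in the
cohort manifest, and equal manifests imply bit-identical outputs.

### What the phantoms do and do not emulate

They reproduce: compositional class structure with realistic Dirichlet
variability, contiguous textured subregions with soft transitions, scanner
blur, bias fields, anisotropic acquisition, noise, and clinical covariates
matching published class-conditional summaries.  They do not reproduce:
prostate zonal anatomy, registration error between sequences, segmentation
variability, non-stationary tissue texture, or inter-scanner effects.
Passing tests therefore show the *method* behaves as intended under its own
assumptions; they say nothing about performance on real cohorts.

## Numerical choices and degenerate inputs

- Population moments throughout; skewness/kurtosis defined as 0 when the
  variance vanishes; image-feature entropies in bits, mutual information in
  nats.
- GLCM correlation is 1 for a single-level matrix; constant regions give
  entropy 0, maximum probability 1, coarseness at the 1e6 cap.
- Equal-frequency binning merges duplicate quantile edges, so heavily tied
  features use fewer bins.
- LASSO CV falls back to fewer folds when a class has fewer members than
  folds; a fully sparse solution falls back to the top mRMR feature.
- K-means ties in CH go to the smaller K; the subsample for K selection is
  seeded.
- Resampling clamps at the volume edge (`mode="nearest"`), so affine fields
  are reproduced exactly only in the interior.
- The decision-curve grid excludes t = 1 (division by zero); calibration
  reduces the bin count with a warning when n < bins.

## Packaged experiment sizes

The experiment scripts and acceptance checks run the default 175-patient
cohort with the clustering scan reduced to K = 2..6, 5 restarts and a
20,000-voxel subsample, and recovery experiments on pooled cohorts of
12–16 phantoms; these sizes are the package's standard configuration for
its bundled experiments, chosen so a full run stays in the minutes range
on one core.  All are ordinary config keys (`ClusteringConfig`), and the
library defaults remain K = 2..9 with a 100,000-voxel cap.

## Known limitations

- **Voxel-wise habitat recovery is information-limited.**  With a 5 mm
  window, ~1 mm transition zones and subregions a few hundred to a few
  thousand voxels in size, a large fraction of lesion voxels sit within
  window reach of a habitat interface, where the window statistics are
  mixtures.  Decoding voxels by *true* habitat centroids (an oracle no
  clustering can beat on average) plateaus around ARI ≈ 0.7–0.8 on these
  phantoms, and K-means assignment lands near ARI ≈ 0.6: habitat *number*,
  cohort-level composition and the downstream classification signal are
  recovered reliably, but voxel-exact maps are not, and the corresponding
  strict map-recovery check (ARI ≥ 0.8) fails by design of the geometry,
  not by implementation error.  Larger lesions or a smaller kernel radius
  raise the ceiling.
- The bias corrector removes polynomial fields only; strongly non-smooth
  coil profiles need a substituted N4 implementation.
- Squared-loss LASSO on a 0/1 label is the stated selection rule and is
  kept as the default even though logistic-deviance selection would be the
  more natural statistical choice (available via `lasso_loss="deviance"`).
- The published split ratio is stated as 7:3 while the reported training
  and test sizes (140/35 of 175) imply 8:2; the ratio is a config parameter
  (default 0.7) and the discrepancy is left unresolved.
- With three habitats and K selected by CH there is no guarantee that a
  real cohort yields K = 3; the pipeline stores the full CH curve for
  inspection.
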