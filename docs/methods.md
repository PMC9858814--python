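# Methods

This note documents the models, conventions and design choices behind
`radigen`, in the order the pipeline runs them.

## Kinetic maps

Percentage enhancement and signal-enhancement ratio are pure voxel
arithmetic on the four co-registered timepoints:

    PE_early = 100 · (I_early − I_pre) / I_pre
    SER_t    = (I_early − I_pre) / (I_t − I_pre)

Division guards: a voxel is flagged invalid when its denominator falls below
ε = 1e-6 × the mean |denominator-reference| in the region of interest
(the pre-contrast mean for PE, likewise for the SER difference). Invalid
voxels are set to 0 and carried in an explicit `invalid_voxel_mask` rather
than propagated as NaN, so feature extraction always sees finite arrays and
can simply exclude those voxels. On noise-free synthetic cohorts the
invalid set is empty.

Pipeline order is fixed as: maps on the native co-registered grid → per-image
μ ± 3σ histogram remap (within the tumor mask, affine to [0, 100]) → 1 mm
isotropic resampling → feature extraction. Computing the maps before any
intensity remapping keeps PE/SER in their physical, ratio-interpretable
units; the alternative order (remap first) is exposed as
`maps.normalize_before_maps` in the pipeline config. The remap target range
[0, 100] is an arbitrary affine choice fixed for reproducibility.

Resampling uses a cubic B-spline for intensities (`scipy.ndimage`
`map_coordinates`, order 3) and nearest-neighbor with re-binarization for
masks. The output grid preserves the physical span of voxel centers.
Spline boundary ringing decays geometrically away from volume edges; tests
therefore check interpolation accuracy in the deep interior.

## Radiomic features (174)

14 shape + (18 first-order + 22 GLCM) × 4 images. Conventions that needed
fixing where multiple standards coexist:

- **Meshing.** The binary mask is anti-aliased with a 1-voxel-SD Gaussian
  before marching cubes (level 0.5). Without this, the staircase surface of
  a voxelized ball inflates surface area by ~8% and caps sphericity near
  0.92; with it a radius-10 ball measures sphericity ≈ 0.997. Mesh volume
  comes from the divergence theorem over signed tetrahedra.
- **Axis lengths.** 4·sqrt(eigenvalue) of the physical voxel-coordinate
  covariance, eigenvalues sorted descending (full axis length). Note a
  solid ellipsoid with semi-axis a has coordinate variance a²/5 along that
  axis, so its measured axis length is 4a/√5 ≈ 1.79a, not 2a; Elongation
  and Flatness (ratios) are unaffected.
- **2-D diameters.** Computed per-slice from in-plane boundary voxel
  centers (convex-hull pruned), maximized over slices, for each of the
  three orthogonal plane families.
- **Discretization.** Equal-width binning into 32 levels spanning the
  within-mask range (exposed as `features.n_bins`). A fixed bin count is
  robust across the four image types, whose ranges differ by orders of
  magnitude. First-order Mean/Median/percentiles use raw intensities and
  are invariant to binning; Entropy/Uniformity and all GLCM features depend
  only on the binned histogram.
- **GLCM.** Distance 1, the 13 unique 3-D offsets, both voxels in-mask,
  symmetrized, summed over directions, then normalized — one aggregated
  matrix, deterministic and rotation-invariant for axis-aligned rotations.
  Entropies are base-2 with 0·log0 := 0. Correlation of a flat region is 1
  by convention. Kurtosis is the uncorrected moment ratio (Gaussian → 3).

## Expression scoring

- **Normalization.** Median-of-ratios size factors over genes with an
  all-positive geometric mean; expression is log2(count/factor + 1).
- **Gene ranking.** Welch t between the high and low feature groups on the
  log scale. A full negative-binomial GLM is deliberately not used: GSEA
  consumes only a monotone ranking, and the Welch t on normalized log
  counts is a simple, fast, deterministic statistic with the same ordering
  behavior for this purpose. Genes with zero variance in both groups but a
  mean shift are placed just beyond the finite statistics with the correct
  sign; exact ties in the final ordering break by gene ID.
- **GSEA.** Weighted KS running sum: hits add |t|^p / Σ_members|t|^p
  (p = 1), misses subtract 1/(N − m); the ES is the signed extreme of the
  walk. If all member stats are zero the walk falls back to unweighted
  hits with a warning.
- **GSEA null.** Two permutation schemes are provided. The *gene* null
  (random same-size gene subsets) is the default of the standalone
  `gsea_significance` and is appropriate when genes are approximately
  exchangeable. The association stage defaults to the *phenotype* null —
  group labels are reshuffled and the entire ranking recomputed per
  permutation (vectorized, so 200 permutations cost about as much as one
  matrix product) — because co-expressed gene modules violate gene
  exchangeability: measured on synthetic null cohorts whose unplanted
  pathways are still coherent expression modules, the gene null flags the
  majority of pairs while the phenotype null stays at the nominal 5% level.
  Nominal p is the same-sign null fraction with |ES| ≥ |observed|; NES
  divides ES by the same-sign null mean |ES|; q-values are
  Benjamini–Hochberg across pathways (per feature).
- **GSVA.** Per-gene kernel CDF across samples (Poisson kernel with
  rate x + 0.5 for integer counts, Gaussian with bandwidth sd/4
  otherwise), per-sample gene ranking by decreasing level statistic,
  symmetric rank weights |N/2 − rank|^τ with τ = 1, and a weighted KS walk
  per sample scored as max positive deviation + max negative deviation
  (max-diff), giving scores in (−1, 1). Constant gene rows are dropped
  with a warning; at least 4 samples are required.

## Association analysis

High/low groups split at the median with ties assigned low
(deterministic; the tie rule bounds the group-size gap by twice the tie
count). Significance regime is configurable — raw p < 0.05 (default, the
regime under which the published pair counts are described) or BH q < 0.05
— and every summary records which regime produced it. Pearson p-values are
two-sided on the t distribution with df = n − 2 and are deliberately not
multiplicity-corrected. Percentages and per-pathway/per-feature means round
half-up to one decimal. The qualitative stage canonicalizes sample order
internally, so results are invariant to the row order of the inputs.
Cohort category profiles are compared with Pearson's chi-squared test
(no continuity correction), with a warning when an expected cell is < 1.

## Prediction

Random-forest regression (scikit-learn) of one pathway's GSVA score from
the feature table. The five preprocessing toggles are independent booleans;
everything data-driven — z-score parameters, target-bin oversampling,
sample weights, top-15 feature selection — is fit inside training folds
only, and a mutation test asserts that corrupting test-set targets leaves
all training artifacts unchanged. The 10-bin oversampler retains every
original index and upsamples each non-empty equal-width target bin to the
largest bin's count. Grid search minimizes 5-fold CV mean MAE over the
stated grid (untuned default: 500 trees, squared error, unlimited depth).
The CV 95% CI is the normal approximation mean ± 1.96·SD over the five
fold MAEs — intentionally wide at 5 folds. MAE is reported as
mean |y − ŷ| × 100, i.e. percentage points on the [−1, 1] enrichment-score
scale. CV folds are seeded, not stratified.

## Synthetic cohorts

The generator is the package's test bed and defines the conditions under
which calibration and power are measured.

- **Phantoms.** Lobulated ellipsoids: semi-axes drawn from the configured
  radius range, surface perturbed by a unit-variance Gaussian random field
  (4-voxel smoothing) scaled by 5% of radius per unit lobulation; largest
  6-connected component, hole-filled, required to keep a 1-voxel margin.
- **Kinetics.** I(t) = I_pre (1 + A·(1 − e^{−kt}) e^{−wt}) at t = 0, 1, 3,
  5 min — a mono-exponential wash-in times exponential wash-out chosen for
  closed-form verifiability, not pharmacokinetic (Tofts-type) realism. The
  voxel amplitude modulates A by a smooth random field with relative SD =
  the heterogeneity parameter; relative Gaussian noise (default 2%) is
  added to every volume.
- **Latents and planting.** Four standard-normal latent phenotypes (size,
  wash-in, wash-out, heterogeneity) map into parameter ranges by the
  probability integral transform. A planted pair (latent, pathway, ρ) sets
  pathway activity = ρ·z + sqrt(1 − ρ²)·ε — a Gaussian copula, so ρ is
  exact in latent space and all attenuation through imaging/expression
  noise is measured, never assumed.
- **Expression.** Counts are gamma-Poisson (negative binomial,
  Var = μ + 0.2μ²) with log-mean baseline ~ U(2, 6) (natural log), member
  genes shifted by 1.0 × activity, per-sample library sizes ~ U(0.7, 1.3).
  Gene sets (default 10 sets of 20–40 genes) are disjoint, which keeps
  truth accounting exact. Defaults were chosen once as typical of bulk
  RNA-seq moderate-expression genes and moderate pathway effects.
- **Feature-level fast path.** `simulate_association_cohort` skips phantom
  rendering: each "feature" is its own latent observed with Gaussian noise
  (SD 0.35, i.e. feature–latent correlation ≈ 0.94). Calibration and power
  studies of the association and prediction stages use this path with
  n = 150 patients, 20 features, 10 pathways, 1000 genes and 200
  permutations; the imaging stages are exercised end-to-end on smaller
  rendered cohorts (40 patients, 24³ grids) where the geometry, not the
  statistics, is under test.

What the synthetic data does *not* emulate: scanner bias fields, partial
volume effects, registration error, FPKM-scale expression, overlapping
pathways, batch effects. Passing tests demonstrate the statistical
machinery is calibrated and recovers planted effects under the stated
model; they do not certify performance on clinical data.

## Numerical conventions

- 0·log0 := 0 everywhere; entropies base 2; test statistics natural scale.
- Every stochastic operation takes an explicit seed; the pipeline fans one
  global seed out per stage by stable hashing of the stage name.
- Rounding for reported percentages/means: half-up, one decimal.
- Degenerate inputs fail loudly (empty/planar masks, constant features,
  all-zero rankings) or are flagged and skipped with warnings where the
  surrounding analysis can continue (degenerate median splits,
  zero-variance Pearson pairs).

## Known limitations

- The GLCM catalog is the standard 22-feature set; sparse masks with very
  few co-occurring pairs make the higher-order statistics noisy.
- The phenotype-permutation GSEA p-value has resolution 1/n_perm (0.005 at
  the default 200); q-values inherit that granularity.
- GSVA here is method-compatible, not bit-compatible, with other
  implementations (kernel and scoring conventions documented above).
- The 95% CI on CV MAE uses a normal approximation over 5 fold MAEs and is
  accordingly unstable; it is reported for comparability, not inference.
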