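# radigen

Radiogenomic association analysis for breast DCE-MRI and bulk RNA-seq:
from four-timepoint dynamic contrast-enhanced MRI tumor volumes and a gene
expression count matrix to imaging–pathway association tables and
random-forest predictors of per-patient pathway activity.

## Who this is for

Imaging and computational-biology groups studying how quantitative imaging
phenotypes (radiomics) relate to transcriptomic programs — e.g. whether
tumors with high texture entropy on late-enhancement maps also show elevated
cell-cycle pathway activity — and who want every stage of that analysis as
tested, reusable, scriptable Python rather than a one-off notebook.

## What it computes

**Kinetic parametric maps.** With `I_pre`, `I_early` (~1 min), `I_middle`
(~3 min), `I_late` (~5 min) co-registered volumes, voxel-wise

    PE_early = 100 · (I_early − I_pre) / I_pre
    SER_t    = (I_early − I_pre) / (I_t − I_pre),   t ∈ {middle, late}

PE measures early contrast uptake; SER characterizes wash-out. Zero
denominators are flagged in an explicit invalid-voxel mask. Images are then
remapped to the within-mask μ ± 3σ window and resampled to 1 mm isotropic
resolution (cubic B-spline).

**Radiomics.** A 174-feature IBSI-style catalog: 14 shape features from a
marching-cubes mesh and coordinate PCA of the mask, plus 18 first-order and
22 gray-level co-occurrence matrix (GLCM) features from each of the four
images (pre, PE-early, SER-middle, SER-late): 14 + 4·(18 + 22) = 174.

**Enrichment.** Median-of-ratios size factors; Welch-t gene ranking between
high/low feature groups; GSEA — the weighted Kolmogorov–Smirnov running-sum
enrichment score with a permutation null, nominal p, NES and
Benjamini–Hochberg q; and GSVA per-sample enrichment scores (kernel CDF →
symmetric rank statistic → weighted KS walk, max-diff scoring).

**Association.** Qualitative: median-split GSEA of every feature against
every pathway. Quantitative: Pearson r between each feature and each
pathway's GSVA score (two-sided t test, df = n−2). Summaries count
significant pairs and unique pathways/features per feature category, and
two cohorts' category profiles are compared with a chi-squared test.

**Prediction.** Random-forest regression of a pathway's GSVA score from the
radiomic features, with five preprocessing toggles (z-scoring, target-bin
oversampling, top-15 feature selection, sample weighting, grid-search
tuning), 5-fold CV mean absolute error with a 95% CI, and held-out test
MAEs. MAE is reported in percentage points of enrichment score.

**Synthetic cohorts.** `radigen.synthetic` generates lobulated ellipsoid
tumor phantoms with closed-form enhancement kinetics, negative-binomial
expression counts whose pathway activity is correlated with the imaging
latents at planted effect sizes, and the ground-truth record needed to
measure calibration and power of the whole pipeline.

## Worked example

```python
import radigen as rg

# a 150-patient synthetic cohort with one planted association:
# the latent behind feat03 drives pathway SET02 at rho = 0.6
feats, counts, sets, truth = rg.simulate_association_cohort(
    n_patients=150, n_features=20,
    expr_cfg=rg.ExpressionConfig(n_genes=1000, n_sets=10, seed=7),
    planted_pairs=[("feat03", "SET02", 0.6)], seed=7,
)

qual = rg.qualitative_associations(feats, counts, sets, n_perm=200, seed=7)
es = rg.gsva_scores(counts, sets)
quant = rg.quantitative_associations(feats, es)

print(qual.qualitative.loc[("feat03", "SET02"), ["es", "pval"]])
print(quant.quantitative.loc[("feat03", "SET02"), ["r", "pval"]])
```

prints (seed 7):

```
es      1.0
pval    0.0
Name: (feat03, SET02), dtype: float64
r       5.693427e-01
pval    2.908894e-14
Name: (feat03, SET02), dtype: float64
```

The planted feature–pathway pair is recovered on both routes: every member
gene of SET02 ranks above every non-member in the high-vs-low feat03
comparison (enrichment score 1.0, empirical p below the permutation
resolution of 1/200), and the Pearson correlation between the feature and
the pathway's per-sample GSVA score is r ≈ 0.57 — the planted latent
correlation of 0.6 attenuated by observation noise in the feature and in
the expression counts.

The full imaging path is driven by the CLI:

```bash
radigen simulate --out cohort --seed 3        # phantoms + counts + gene sets
radigen maps --in cohort --out cohort         # PE / SER maps
radigen run --config pipeline.yaml            # everything end to end
```

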