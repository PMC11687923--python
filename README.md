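# latentgwas

GWAS on learned low-dimensional imaging phenotypes, end to end and at desk
scale. The package is aimed at imaging-genetics researchers who want to
prototype, test, or teach the "transfer-learning GWAS" workflow — extract
deep-network features from brain MRI volumes, reduce them to principal
components, and treat those components as quantitative traits — without
access-restricted biobank data: a seeded synthetic-cohort generator stands
in for the real cohort, and every downstream method is implemented and
tested against planted ground truth.

## What it does

* **Synthetic cohorts** (`latentgwas.synthdata`) — diploid genotype panels
  in LD blocks (thresholded AR(1) Gaussian copula, tunable MAF and r²),
  template-space 3D volumes whose ellipsoidal ROIs respond additively to
  genotype, age and sex, a continuous dementia-like score tracking the
  "ventricle" ROI, phenotype banks for PheWAS, and paired summary
  statistics drawn from the expectation model that LD-score regression
  assumes.
* **Feature learning** (`latentgwas.features`) — a multi-task conditional
  variational autoencoder over NumPy with loss
  `1·MSE(recon) + 1e-4·KLD + 1e-2·MSE(dementia prediction)`, decoder and
  prediction head conditioned on standardized age and sex; a
  slice-averaging wrapper for any user-supplied 2D feature function; PCA
  reduction (centering only) with explained-variance ratios.
* **GWAS** (`latentgwas.gwas`) — variant QC (MAF ≥ 0.1%, HWE at α = 0.001,
  missingness ≤ 10%, windowed LD pruning at r² = 0.8), covariate-adjusted
  least-squares association scans via Frisch–Waugh residualization,
  Bonferroni thresholds, greedy distance-based clumping (±250 kb, index
  p ≤ 1e-9), min-p aggregation across traits, locus matching, and a
  discovery/replication split.
* **Interpretation** (`latentgwas.interpret`) — PheWAS with automatic
  linear/logistic dispatch and rank-inverse-normal transforms, voxel-wise
  t-statistic maps (`t = r·√((n−2)/(1−r²))`) with Bonferroni voxel
  thresholds, per-ROI significant-voxel fractions and variance-explained
  ratios.
* **Polygenic scores** (`latentgwas.pgs`) — clumping + thresholding PGS
  with validation-fold threshold selection, allele-flip-aware scoring,
  nested multi-PGS evaluation on a 60/40 split, and the prediction-swap
  permutation test (1000 permutations) for R² differences.
* **Genetic correlation** (`latentgwas.gencorr`) — bias-adjusted windowed
  LD scores, LD-score-regression heritability (`E[χ²] = 1 + N·h²·ℓ/M`)
  and cross-trait genetic correlation with block-jackknife standard
  errors, and the shared-region z-product screen
  (`|z₁·z₂| > 15`, focal p < 1e-4, ±250 kb regions).
* **Pipeline & I/O** (`latentgwas.pipeline`, `latentgwas.io`) — dosage TSV
  with a variant sidecar, a minimal VCF dialect, NIfTI volume stacks with
  an `.npz` fallback, summary-statistics/locus/weights TSVs, a YAML config
  with unknown-key rejection, per-stage seed fan-out, and a SHA-256
  manifest of every artifact.

A thin CLI mirrors the stages: `latentgwas simulate | train | encode |
pca | qc | scan | clump | phewas | spm | pgs | gencorr | run`.

## Worked example

`examples/03_gwas_scan_and_clump.py` simulates 2000 samples × 1000 variants,
plants one causal variant at 4% explained variance, scans and clumps:

```
QC: {'input_variants': 1000, 'removed': {'maf': 0, 'missingness': 0,
    'hwe': 0, 'ld_prune': 0}, 'surviving_variants': 1000, 'samples_removed': 0}
top hit: rs251 at 1:25000001 p=1.63e-17 (planted: rs251)
family-wise index threshold for 20 traits: 2.5e-09
1 independent locus/loci; members of the first: ['rs251'] ...
```

The scan's smallest p lands exactly on the planted variant, and clumping
collapses its LD block into a single locus whose index is the truth. The
`2.5e-9` line is the Bonferroni-corrected index threshold when 20 latent
traits share the genome-wide α = 5e-8.

`examples/05_ldsc_and_shared_regions.py` simulates summary statistics under
the LD-score-regression model and refits them:

```
h2 = 0.212 +/- 0.008 (truth 0.2), intercept 0.734 (1.0 means no confounding)
rg = 0.453 +/- 0.019 (truth 0.5)
```

Estimates recover the generating heritability and genetic correlation
within a couple of standard errors; the free intercept absorbs
confounding (none is simulated, so it sits near 1 on average).

Each `examples/*.py` script is a runnable narrative for one capability.

## Method notes

The scientific choices — what the generator emulates and what it leaves
out, the association model standing in for a mixed model, the simplified
LDSC weighting, problem sizes — are documented in `docs/methods.md`.
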