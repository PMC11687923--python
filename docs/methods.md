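# Methods

This note records the scientific and numerical choices behind `latentgwas`:
what each model assumes, which parameters matter and why their defaults
were chosen, what the synthetic cohort does and does not emulate, and the
known limitations.

## The synthetic cohort

The generator emulates the structure of a population-imaging study at desk
scale, with every quantity controlled by an explicit seed.

**Genotypes.** Each haplotype allele is a thresholded latent Gaussian;
within an LD block of `ld_block_size` variants (default 10) the latents
follow an AR(1) process with parameter `block_corr` (default 0.6), so r²
between genotypes decays geometrically with index distance inside a block
and is ~0 across blocks. Two independent haplotypes per individual mean
every variant sits in Hardy–Weinberg equilibrium regardless of LD. Target
alt-allele frequencies are drawn uniformly from `maf_range` (default
0.05–0.5). Variants are placed 1 kb apart within a block and blocks start
1 Mb apart, so no clumping or pruning window ever spans two blocks — which
makes greedy window algorithms exactly analyzable in tests. Missingness is
uniform and independent of genotype. This is a Gaussian-copula caricature:
it reproduces the two features downstream methods consume (allele
frequency and a tunable, banded r² structure) and nothing else — no
coalescent genealogy, no recombination maps, no allele-frequency spectrum.

**Volumes.** A fixed "template" places `n_rois` axis-aligned ellipsoids at
deterministic positions in a 32³ grid (the rendering, not the method,
bounds the resolution; real pipelines use 96³ or finer after template
registration). Planted effects act additively: a radius effect adds
`beta` voxels to the target ROI's mean radius per alt allele; an intensity
effect adds `beta` intensity units to the ROI's fill value; `age_slope`
(per decade, centered) and `sex_offset` shift all radii;
`age_intensity_slope` adds a *global* intensity offset proportional to
centered age, emulating the age-predictable component of overall scan
brightness; i.i.d. Gaussian voxel noise (`noise_sd`, default 0.1 against a
base ROI intensity of 1) is added last. No bias fields, motion, partial
voluming, or registration error are simulated, so passing tests show the
statistics are computed correctly on idealized data — not that the methods
are robust to real MRI artefacts.

**Dementia-like score.** The score is the rendered "ventricle" ROI's mean
radius, standardized, plus Gaussian noise (sd 0.5). A continuous score was
chosen over an ordinal clinical rating so the prediction head's loss is a
plain squared error; the corresponding real-data target is ordinal, and an
ordinal head would need a different loss.

**Summary statistics.** `simulate_sumstats` draws paired z-scores
per-variant bivariate normal with exactly the second moments the LD-score
regression model assumes: `E[z_i²] = 1 + N_i h²_i ℓ_j/M` and
`E[z1 z2] = √(N1 N2) · rg · √(h²_1 h²_2) · ℓ_j/M`, with no confounding
(intercepts 1 and 0). It simulates the *model*, not a genome: LDSC
recovery tests therefore validate the estimator, not the model's fit to
real data.

## Feature learning

The volumetric extractor is a multi-task conditional VAE with loss

    L = 1·MSE(x̂, x) + 1e-4·KLD(q(z|x) ‖ N(0, I)) + 1e-2·MSE(ŷ, y)

where x̂ is the reconstruction, y the dementia-like score, and both the
decoder and the two-layer prediction head receive the latent concatenated
with standardized age and sex. Training samples z by reparameterization;
encoding at inference returns the latent mean. The reconstruction MSE is
averaged over voxels and batch; the KLD is summed over latent dimensions
and averaged over the batch — with voxel intensities standardized to unit
variance this puts the weighted KLD two to three orders of magnitude below
the reconstruction term, a weak but persistent pressure toward compact
latents.

The network is fully connected (encoder V→64→16·2, mirrored decoder, head
16+2→16→1), trained with Adam (lr 1e-3, batch 32) and explicit NumPy
backpropagation; the backward pass is verified against central finite
differences in the test suite, and a fixed seed reproduces training
bit-for-bit on one machine. A fully-connected architecture was chosen over
convolutions because at 32³ with a few hundred samples the dense encoder
already has more capacity than the data constrains, and it keeps the
hand-written gradient code short and auditable. Desk defaults (latent 16,
epochs 20) replace the reference configuration (latent 128, 500 epochs,
batch 128) that presumes thousands of volumes and accelerator hardware.

**What conditioning does, and when it is visible.** Conditioning the
decoder on age can remove age information from the latent only for image
variation that is *predictable from age* — for the global age-driven
brightness component, a converged conditioned model reconstructs it from
the age input and the KLD pressure strips the (now redundant) encoding,
whereas an unconditioned model must keep it. Variation that merely
*correlates* with age (e.g. radius noise confounded with an age slope)
cannot be removed: the encoder sees only the image and cannot subtract a
component it cannot identify. Empirically the stripping is slow — it is
driven by the 1e-4-weighted KLD gradient — and emerges reliably only after
on the order of a thousand optimizer steps (≈150–200 epochs at n=200,
batch 32), consistent with the reference configuration's 500-epoch budget.
The conditioning tests therefore run at 16³ with a 32-unit hidden layer
and 150 epochs, where that step count is affordable; short 20-epoch runs
at 32³ were observed to leave the comparison at chance.

**Short-run variability.** At 20 epochs with a few hundred samples the
prediction head can overfit latent noise (training MSE below the score's
noise floor), which inflates prediction variance and can push the held-out
R² negative on some cohort draws even while the prediction–truth
correlation stays clearly positive; likewise the 5-seed
conditioned-vs-unconditioned comparison holds its majority on most but not
all cohort draws. Both are finite-training effects that recede with the
longer schedules discussed above, and reported values should be read with
that variability in mind.

**2D route.** `slice_average_encode` applies any user-supplied 2D feature
function to every axial slice and averages the vectors, the standard trick
for applying a 2D pretrained encoder to a volume. No pretrained weights
ship with the package; a seeded random linear projection is the default
stand-in (adequate for pipeline and linearity tests, obviously not a
learned representation).

**PCA.** Features are centered but not variance-scaled before the
eigendecomposition, so explained-variance ratios refer to the latent
features' native scales; component signs are fixed by making each
component's largest-magnitude loading positive. PC scores are standardized
to unit variance before association testing so betas are in trait-SD units.

## Association model

The scan fits, per variant and trait, ordinary least squares of the trait
on dosage plus the full covariate design (intercept, age, sex, batch
dummies, genetic PCs), implemented by residualizing both trait and
mean-imputed dosages on the covariates (Frisch–Waugh) so each trait is one
matrix product; p-values come from the t distribution with n−p−1 degrees
of freedom and are floored at the smallest subnormal rather than 0. A
linear mixed model would additionally absorb cryptic relatedness; at the
simulated scale, population structure is the only confounding axis and the
genotype-PC covariates control it. Zero-variance dosages yield beta 0,
p 1, and a flag column instead of an exception.

QC order is MAF → missingness → HWE → LD-prune, with per-sample
missingness handled before variant statistics. LD pruning is windowed
greedy (500 kb default) keeping the earlier-position variant — a
deterministic tie-break chosen so QC reports are reproducible. Clumping is
greedy by ascending p (ties by chrom, pos): an index needs p ≤ 1e-9 and
claims members at p ≤ 5e-8 within ±250 kb, inclusive, on its chromosome;
positions are 1-based throughout. Replication uses nominal p < 0.05 plus
beta-sign concordance on the index variant in a disjoint split.

## Interpretation

PheWAS reduces a full phenotype-curation decision tree to a two-type
dispatch: declared-continuous phenotypes are rank-inverse-normal
transformed (Blom offset 0.375) and fit by OLS; declared-binary ones by
logistic regression; age and sex are always included; single-class binary
phenotypes are flagged untestable. The Bonferroni threshold spans
n_traits × n_phenotypes and is always computed from (α, n_tests) rather
than quoted.

Voxel SPMs convert per-voxel Pearson correlations to t statistics and
threshold two-sided at α = 0.05 Bonferroni-corrected over in-mask voxels
(constant voxels get t = 0 and a counter). The per-ROI
"significant fraction" is |significant ∩ ROI| / |ROI|; the per-ROI
variance-explained ratio is the variance-weighted mean of per-voxel R²,
Σ r²_v·Var_v / Σ Var_v, which equals 1 exactly when every ROI voxel is an
affine function of the variable and is insensitive to flat background
voxels.

## Polygenic scores

PGS construction is clumping + thresholding: clump at each candidate p
threshold, keep index variants with their marginal betas, select the
threshold by validation R² on a held-out fold of the tuning cohort (most
stringent non-empty threshold when no tuning data are given). A
continuous-shrinkage method would need an external LD reference and a
Gibbs sampler; C+T exercises the same interfaces and is exactly testable.
Scoring matches on variant id with an effect-allele flip rule (d → 2−d
when effect/other alleles are swapped); strand-ambiguous A/T and C/G
variants are scored as-is with a warning since the synthetic panel
controls strand.

The multi-PGS comparison fits base (covariates + trait-specific PGS) and
extended (+ extra PGS) linear models on a 60% split and compares R² on the
held-out 40%. The permutation test swaps, per test sample with a fair
coin, which model's prediction goes into each of two hybrid vectors, and
uses the two-sided add-one p over 1000 hybrid ΔR² values; sidedness is not
dictated by the source material, and two-sided is the conservative choice.

## LD-score regression

LD scores are windowed (±1 Mb) sums of r̃² = r² − (1−r²)/(n−2), the
standard small-sample bias adjustment, self-term included. Heritability is
the slope of a weighted regression of χ² on ℓ (free intercept) rescaled by
M/N; weights are a two-step scheme — pass one with 1/ℓ, pass two with the
model-implied inverse variance 1/(ℓ·2(1+Nĥ²ℓ/M)²) — a simplified version
of the reference estimator's heteroskedasticity weighting, validated here
by parameter recovery (mean ĥ² within 0.01 of truth over 50 simulations at
M=5000, N=20000). Genetic covariance comes from the analogous z₁z₂-on-ℓ
regression; rg = gencov/√(h²₁h²₂), clipped to ±1.25 with the raw value
retained, undefined (flagged) when either ĥ² ≤ 0. Standard errors are
delete-one block jackknives over 20 contiguous position-ordered blocks;
variants are sorted internally so the fit is invariant to input row order.

The shared-region screen takes three summary-statistics tables (focal,
trait b, trait c), keeps variants with focal p < 1e-4 and both
|z_focal·z_b| and |z_focal·z_c| above 15, optionally constrains each
z-product's sign to match a given genetic-correlation sign, and groups
candidates greedily around the variant with the largest |z_focal·z_b|
within ±250 kb. The p-value condition is applied to the focal trait, and
"central" is defined by the trait-b z-product — both underdetermined by
the source description and fixed here for reproducibility.

## Pipeline, seeding, formats

One global seed fans out to per-stage child seeds as the first four bytes
of SHA-256 of `"<seed>:<stage>"` mod 2³¹, so any stage can be re-run in
isolation. Each run writes `manifest.json` mapping artifact paths to
SHA-256 content hashes; all float output uses fixed formats so identical
configurations produce identical hashes. Dosage TSVs round-trip
bit-exactly (dosages serialized by `repr`); the minimal VCF dialect maps
GT to dosage with half-calls and `./.` as missing, and all parsers report
file and line on malformed input.

## Problem sizes and limitations

The shipped demo and test sizes — 500–2000 samples, 2000 variants, 32³
volumes, 16-dimensional latents, 5–20 training epochs — were chosen so a
full pipeline run and the complete test suite execute on a single CPU in
minutes while keeping every planted effect at ≥80% detection power.
Known limitations, beyond the generator idealizations above: the
association model does not handle relatedness; LD pruning and clumping are
distance-based only (no r² condition on clump membership); logistic PheWAS
fits can fail to converge under separation (flagged, not fixed); the
LDSC weighting scheme is simplified and its jackknife assumes
exchangeable blocks; and the VAE's conditioning effect on latent–age
correlation requires training to near-convergence, as discussed above.
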