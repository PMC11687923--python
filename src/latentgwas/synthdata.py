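"""Synthetic study generator: genotypes in LD blocks, template-registered
volumes with planted genetic effects, covariates, a dementia-like score,
phenotype banks, and model-faithful GWAS summary statistics.

Everything is driven by an explicit integer seed and is bit-reproducible.
The generator emulates the structure of a population-imaging cohort: diploid
genotypes with block-wise linkage disequilibrium, 3D "brain" volumes in a
shared template space whose labelled ROIs respond additively to genotype,
age and sex, and paired summary statistics following the expectation model
that LD-score regression assumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    MISSING,
    CovariateTable,
    EffectSpec,
    GenotypePanel,
    SummaryStats,
    ValidationError,
    VolumeStack,
)

__all__ = [
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_phenobank",
    "simulate_sumstats",
    "roi_template",
    "VENTRICLE_LABEL",
]

#: ROI label designated as the "ventricle" driving the dementia-like score.
VENTRICLE_LABEL = 1

# Base-pair layout: variants within an LD block sit 1 kb apart, blocks start
# 1 Mb apart, so a block of up to 250 variants spans < 250 kb and different
# blocks never share a clumping window.
_INTRA_BLOCK_BP = 1_000
_BLOCK_STRIDE_BP = 1_000_000


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 10,
    block_corr: float = 0.6,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
) -> GenotypePanel:
    """Draw a diploid dosage panel with block-wise LD.

    Each haplotype allele is a thresholded latent Gaussian; within a block
    the latents follow an AR(1) process with parameter ``block_corr``, so
    r^2 decays with index distance inside a block and is ~0 across blocks.
    Two independent haplotypes per sample keep every variant in
    Hardy-Weinberg equilibrium. Missing dosages (sentinel) are dropped in
    uniformly at random at ``missing_rate``.
    """
    if n_samples < 2 or n_variants < 1:
        raise ValueError("need n_samples >= 2 and n_variants >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not 0 <= block_corr < 1:
        raise ValueError("block_corr must lie in [0, 1)")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    if ld_block_size > 240:
        raise ValueError("ld_block_size > 240 would let a block span >= 250 kb")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    # thresholds for alt-allele probability per haplotype
    thresh = sps.norm.ppf(1.0 - mafs)

    def _haplotypes() -> np.ndarray:
        """One latent AR(1) Gaussian per haplotype, thresholded to alleles."""
        z = np.empty((n_samples, n_variants))
        rho = block_corr
        innov = rng.standard_normal((n_samples, n_variants))
        for j in range(n_variants):
            if j % ld_block_size == 0:  # block start: fresh latent
                z[:, j] = innov[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j]
        return (z > thresh[None, :]).astype(float)

    dosages = _haplotypes() + _haplotypes()

    if missing_rate > 0:
        miss = rng.random((n_samples, n_variants)) < missing_rate
        dosages[miss] = MISSING

    block = np.arange(n_variants) // ld_block_size
    within = np.arange(n_variants) % ld_block_size
    pos = 1 + block * _BLOCK_STRIDE_BP + within * _INTRA_BLOCK_BP
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(n_variants)],
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "G",
        }
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypePanel(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# cohort: template ROIs, volumes, covariates, dementia score
# ---------------------------------------------------------------------------

def roi_template(
    volume_shape: tuple[int, int, int], n_rois: int, seed: int = 0
) -> tuple[np.ndarray, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Fixed "template-space" layout of axis-aligned ellipsoidal ROIs.

    Returns the integer label map built from the base geometry and a dict
    ``label -> (center, base_radii)``. Centers sit on a deterministic grid
    jittered by the template seed so that ROIs do not overlap; the label map
    itself is re-derived per sample once radii are modulated.
    """
    if min(volume_shape) < 16:
        raise ValueError("volume_shape must be >= 16 voxels per axis")
    if n_rois < 2:
        raise ValueError("need n_rois >= 2")
    rng = np.random.default_rng(seed)
    shape = np.asarray(volume_shape, float)
    # place centers on a 2x2x2 sub-grid cycling through octants
    octants = np.array(
        [[i, j, k] for i in (0.3, 0.7) for j in (0.3, 0.7) for k in (0.3, 0.7)]
    )
    geometry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r in range(n_rois):
        center = octants[r % 8] * shape + rng.uniform(-1.0, 1.0, size=3)
        base = shape.min() / 10.0 * rng.uniform(0.8, 1.2, size=3)
        geometry[r + 1] = (center, base)
    labels = _label_map(volume_shape, geometry)
    return labels, geometry


def _label_map(shape, geometry, radii_override=None, grid=None) -> np.ndarray:
    if grid is None:
        grid = np.indices(shape).astype(float)
    labels = np.zeros(shape, dtype=int)
    for label, (center, base) in geometry.items():
        radii = base if radii_override is None else radii_override[label]
        d2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        labels[(d2 <= 1.0) & (labels == 0)] = label
    return labels


def simulate_cohort(
    panel: GenotypePanel,
    effects: EffectSpec,
    volume_shape: tuple[int, int, int] = (32, 32, 32),
    n_rois: int = 6,
    seed: int = 0,
    n_genetic_pcs: int = 5,
    age_mean: float = 63.0,
    age_sd: float = 7.5,
    base_intensity: float = 1.0,
    dementia_noise_sd: float = 0.5,
) -> tuple[VolumeStack, CovariateTable, np.ndarray]:
    """Render per-sample volumes with planted genetic/covariate effects.

    ROIs are ellipsoids at fixed template positions. For every planted
    effect, the target ROI's radius (isotropically, in voxels) or mean
    intensity shifts by ``beta`` per alt allele; age (centered, per decade)
    and sex shift it via ``effects.age_slope`` / ``effects.sex_offset``;
    Gaussian voxel noise has sd ``effects.noise_sd``. The dementia-like
    score is a monotone (linear) function of the designated ventricle ROI's
    rendered radius plus Gaussian noise — a continuous stand-in for an
    ordinal clinical dementia rating.
    """
    labels, geometry = roi_template(volume_shape, n_rois, seed=0)
    effects.validate_against(panel.n_variants, list(geometry))
    rng = np.random.default_rng(seed)
    n = panel.n_samples

    age = rng.normal(age_mean, age_sd, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    batch = rng.integers(0, 3, size=n)
    cov = pd.DataFrame(
        {"age": age, "sex": sex, "batch": batch}, index=pd.Index(panel.sample_ids, name="sample_id")
    )
    if n_genetic_pcs > 0:
        G = panel.dosages_imputed()
        Gc = G - G.mean(axis=0)
        k = min(n_genetic_pcs, min(Gc.shape) - 1)
        u, s, _ = np.linalg.svd(Gc, full_matrices=False)
        pcs = u[:, :k] * s[:k]
        for j in range(k):
            cov[f"pc{j + 1}"] = pcs[:, j]
    covariates = CovariateTable(cov)

    dose = panel.dosages_imputed()
    age_c = (age - age_mean) / 10.0  # per decade

    radius_shift = {lab: np.zeros(n) for lab in geometry}
    intensity_shift = {lab: np.zeros(n) for lab in geometry}
    for vi, roi, beta, target in effects.entries:
        bucket = radius_shift if target == "radius" else intensity_shift
        bucket[roi] += beta * dose[:, vi]
    for lab in geometry:
        radius_shift[lab] += effects.age_slope * age_c + effects.sex_offset * sex

    volumes = np.empty((n, *volume_shape), dtype=np.float32)
    vent_radius = np.zeros(n)
    grid = np.indices(volume_shape).astype(float)
    for i in range(n):
        radii = {
            lab: np.maximum(base * (1.0 + radius_shift[lab][i] / base.mean()), 0.5)
            for lab, (center, base) in geometry.items()
        }
        # per-sample label map with modulated radii
        lab_i = _label_map(volume_shape, geometry, radii_override=radii, grid=grid)
        vol = np.zeros(volume_shape, dtype=float)
        for lab in geometry:
            vol[lab_i == lab] = base_intensity + intensity_shift[lab][i]
        if effects.age_intensity_slope:
            vol += effects.age_intensity_slope * age_c[i]
        if effects.noise_sd > 0:
            vol += effects.noise_sd * rng.standard_normal(volume_shape)
        volumes[i] = vol.astype(np.float32)
        vent_radius[i] = radii[VENTRICLE_LABEL].mean()

    dementia = vent_radius - vent_radius.mean()
    sd = dementia.std()
    if sd > 0:
        dementia = dementia / sd
    dementia = dementia + rng.normal(0.0, dementia_noise_sd, size=n)

    stack = VolumeStack(volumes, labels, sample_ids=list(panel.sample_ids))
    return stack, covariates, dementia


def simulate_phenobank(
    anchor: np.ndarray,
    n_continuous: int = 20,
    n_binary: int = 20,
    frac_associated: float = 0.25,
    effect_r2: float = 0.1,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A bank of labelled phenotypes for PheWAS, some tied to ``anchor``.

    The first ``frac_associated`` of each type carries signal: continuous
    phenotypes are ``anchor`` plus noise scaled so the anchor explains
    ``effect_r2`` of variance; binary ones pass ``anchor`` through a
    logistic model. The rest are pure noise. Returns the phenotype table
    and a ``name -> "continuous"|"binary"`` type map.
    """
    rng = np.random.default_rng(seed)
    anchor = np.asarray(anchor, float)
    z = (anchor - anchor.mean()) / (anchor.std() or 1.0)
    n = len(z)
    cols, types = {}, {}
    n_assoc_c = int(round(frac_associated * n_continuous))
    n_assoc_b = int(round(frac_associated * n_binary))
    noise_scale = np.sqrt((1 - effect_r2) / effect_r2) if effect_r2 > 0 else np.inf
    for j in range(n_continuous):
        name = f"cont{j + 1:03d}"
        if j < n_assoc_c:
            cols[name] = z + noise_scale * rng.standard_normal(n)
        else:
            cols[name] = rng.standard_normal(n)
        types[name] = "continuous"
    for j in range(n_binary):
        name = f"bin{j + 1:03d}"
        if j < n_assoc_b:
            logit = np.sqrt(effect_r2 / (1 - effect_r2)) * np.pi / np.sqrt(3) * z
            p = 1.0 / (1.0 + np.exp(-logit))
            cols[name] = (rng.random(n) < p).astype(float)
        else:
            cols[name] = (rng.random(n) < 0.5).astype(float)
        types[name] = "binary"
    index = pd.Index(sample_ids, name="sample_id") if sample_ids is not None else None
    return pd.DataFrame(cols, index=index), types


# ---------------------------------------------------------------------------
# summary statistics under the LD-score-regression expectation model
# ---------------------------------------------------------------------------

def simulate_sumstats(
    ld_scores: np.ndarray,
    n1: int,
    n2: int,
    h2_1: float,
    h2_2: float,
    rg: float,
    n_variants: int | None = None,
    seed: int = 0,
    variant_map: pd.DataFrame | None = None,
) -> tuple[SummaryStats, SummaryStats]:
    """Draw paired z-scores from the model LD-score regression assumes.

    Per variant j with LD score l_j and M variants total::

        E[chi^2_j]    = 1 + n_i * h2_i * l_j / M          (each trait)
        E[z1_j z2_j]  = sqrt(n1 n2) * rg * sqrt(h2_1 h2_2) * l_j / M

    z-pairs are bivariate normal with those second moments (no confounding:
    intercepts 1 and 0), p two-sided from z.
    """
    ld = np.asarray(ld_scores, float)
    if (ld < 1.0 - 1e-9).any():
        raise ValueError("LD scores must be >= 1 elementwise")
    for h2 in (h2_1, h2_2):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
    if not -1.0 <= rg <= 1.0:
        raise ValueError("rg must lie in [-1, 1]")
    M = int(n_variants) if n_variants is not None else len(ld)
    if len(ld) > M:
        raise ValueError("more LD scores than the stated variant count M")

    rng = np.random.default_rng(seed)
    v1 = 1.0 + n1 * h2_1 * ld / M
    v2 = 1.0 + n2 * h2_2 * ld / M
    c = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * ld / M
    # Cholesky of [[v1, c], [c, v2]] per variant
    e1, e2 = rng.standard_normal((2, len(ld)))
    z1 = np.sqrt(v1) * e1
    with np.errstate(invalid="ignore"):
        a = c / np.sqrt(v1)
    rem = np.maximum(v2 - a**2, 0.0)
    z2 = a * e1 + np.sqrt(rem) * e2

    if variant_map is None:
        block = np.arange(len(ld)) // 50
        within = np.arange(len(ld)) % 50
        variant_map = pd.DataFrame(
            {
                "id": [f"rs{j + 1}" for j in range(len(ld))],
                "chrom": "1",
                "pos": (1 + block * _BLOCK_STRIDE_BP + within * _INTRA_BLOCK_BP).astype(int),
                "ref": "A",
                "alt": "G",
            }
        )

    out = []
    for z, n, tag in ((z1, n1, "trait1"), (z2, n2, "trait2")):
        se = 1.0 / np.sqrt(n)
        p = np.clip(2.0 * sps.norm.sf(np.abs(z)), 5e-324, 1.0)
        table = pd.DataFrame(
            {
                "CHR": variant_map["chrom"].to_numpy(),
                "POS": variant_map["pos"].to_numpy(),
                "ID": variant_map["id"].to_numpy(),
                "A1": variant_map["alt"].to_numpy(),
                "A2": variant_map["ref"].to_numpy(),
                "BETA": z * se,
                "SE": se,
                "Z": z,
                "P": p,
                "N": n,
                "MAF": 0.5,
            }
        )
        out.append(SummaryStats(table, trait=tag))
    return out[0], out[1]
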