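"""Pipeline driver: configuration, per-stage seeding, logging, and the
end-to-end run producing a manifest of content-hashed outputs.

One global seed fans out to per-stage child seeds via a stated derivation
(SHA-256 of ``"<global_seed>:<stage>"`` reduced mod 2^31), so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gencorr, gwas, interpret, io as lgio, pgs as pgsmod, synthdata
from .features import CVAEConfig, encode_volumes, fit_pca, train_cvae
from .types import CovariateTable, EffectSpec

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_config"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("synthdata", "features", "gwas", "interpret", "pgs", "gencorr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed for one stage (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SynthParams:
    n_samples: int = 500
    n_variants: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 10
    block_corr: float = 0.6
    missing_rate: float = 0.01
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_rois: int = 6
    n_causal: int = 5
    causal_beta: float = 0.4
    age_slope: float = 0.3
    sex_offset: float = 0.2
    noise_sd: float = 0.1
    n_phenotypes: int = 40


@dataclass
class FeatureParams:
    latent_dim: int = 16
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3
    lambda_recon: float = 1.0
    lambda_kld: float = 1e-4
    lambda_pred: float = 1e-2
    n_pcs: int = 10


@dataclass
class GwasParams:
    maf_min: float = 0.001
    hwe_alpha: float = 0.001
    miss_max: float = 0.1
    prune_r2: float = 0.8
    prune_window_bp: int = 500_000
    clump_window_bp: int = 250_000
    index_p: float = 1e-9
    member_p: float = 5e-8
    genomewide_alpha: float = 5e-8


@dataclass
class PgsParams:
    train_frac: float = 0.6
    n_perm: int = 1000
    p_thresholds: tuple[float, ...] = (5e-8, 1e-6, 1e-4, 1e-2)


@dataclass
class GencorrParams:
    ld_window_bp: int = 1_000_000
    shared_p_max: float = 1e-4
    shared_zprod_min: float = 15.0


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration; unknown keys are rejected on load."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    verbosity: str = "INFO"
    synth: SynthParams = field(default_factory=SynthParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    gwas: GwasParams = field(default_factory=GwasParams)
    pgs: PgsParams = field(default_factory=PgsParams)
    gencorr: GencorrParams = field(default_factory=GencorrParams)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


_SECTION_TYPES = {
    "synth": SynthParams,
    "features": FeatureParams,
    "gwas": GwasParams,
    "pgs": PgsParams,
    "gencorr": GencorrParams,
}


def _build_section(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], val or {})
        elif key == "stages":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the enabled stages in order and write a hash manifest.

    Each stage reads only artifacts written by earlier stages (or, when run
    standalone, pre-existing files in ``out_dir``). The manifest maps each
    output path (relative to ``out_dir``) to its SHA-256; it is written to
    ``manifest.json`` and returned.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    state: dict = {}

    stage_fns = {
        "synthdata": _stage_synth,
        "features": _stage_features,
        "gwas": _stage_gwas,
        "interpret": _stage_interpret,
        "pgs": _stage_pgs,
        "gencorr": _stage_gencorr,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        seed = stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            outputs.extend(stage_fns[stage](config, out, seed, state))
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    sp = config.synth
    panel = synthdata.simulate_genotypes(
        sp.n_samples, sp.n_variants,
        maf_range=(sp.maf_low, sp.maf_high),
        ld_block_size=sp.ld_block_size,
        block_corr=sp.block_corr,
        missing_rate=sp.missing_rate,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    n_blocks = sp.n_variants // sp.ld_block_size
    causal_blocks = rng.choice(n_blocks, size=min(sp.n_causal, n_blocks), replace=False)
    causal_idx = sorted(int(b * sp.ld_block_size) for b in causal_blocks)
    rois = list(range(1, sp.n_rois + 1))
    entries = [
        (vi, rois[k % len(rois)], sp.causal_beta, "radius")
        for k, vi in enumerate(causal_idx)
    ]
    effects = EffectSpec(
        entries=entries, age_slope=sp.age_slope, sex_offset=sp.sex_offset, noise_sd=sp.noise_sd
    )
    volumes, covariates, dementia = synthdata.simulate_cohort(
        panel, effects, volume_shape=tuple(sp.volume_shape), n_rois=sp.n_rois, seed=seed + 2
    )
    bank, types = synthdata.simulate_phenobank(
        dementia, n_continuous=sp.n_phenotypes // 2, n_binary=sp.n_phenotypes // 2,
        seed=seed + 3, sample_ids=panel.sample_ids,
    )
    state.update(panel=panel, volumes=volumes, covariates=covariates,
                 dementia=dementia, phenobank=(bank, types), causal_idx=causal_idx)

    paths = list(lgio.write_genotypes(panel, out / "genotypes"))
    paths += lgio.write_volumes(volumes, out / "volumes", format="nifti")
    paths.append(lgio.write_covariates(covariates, out / "covariates.tsv"))
    dem = pd.DataFrame({"sample_id": panel.sample_ids, "dementia_score": dementia})
    dem.to_csv(out / "dementia.tsv", sep="\t", index=False, float_format="%.12g")
    paths.append(out / "dementia.tsv")
    bank.to_csv(out / "phenobank.tsv", sep="\t", float_format="%.12g")
    paths.append(out / "phenobank.tsv")
    with open(out / "phenotypes.types.json", "w") as fh:
        json.dump(types, fh, indent=0, sort_keys=True)
    paths.append(out / "phenotypes.types.json")
    with open(out / "truth.json", "w") as fh:
        json.dump({"causal_variant_indices": causal_idx}, fh)
    paths.append(out / "truth.json")
    return paths


def _require(state: dict, out: Path, key: str):
    if key in state:
        return state[key]
    loaders = {
        "panel": lambda: lgio.read_genotypes(out / "genotypes"),
        "volumes": lambda: lgio.read_volumes(out / "volumes"),
        "covariates": lambda: lgio.read_covariates(out / "covariates.tsv"),
        "dementia": lambda: pd.read_csv(out / "dementia.tsv", sep="\t")["dementia_score"].to_numpy(),
    }
    state[key] = loaders[key]()
    return state[key]


def _stage_features(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    fp = config.features
    volumes = _require(state, out, "volumes")
    covariates = _require(state, out, "covariates")
    dementia = _require(state, out, "dementia")
    cvae_cfg = CVAEConfig(
        latent_dim=fp.latent_dim, epochs=fp.epochs, batch_size=fp.batch_size, lr=fp.lr,
        lambda_recon=fp.lambda_recon, lambda_kld=fp.lambda_kld, lambda_pred=fp.lambda_pred,
        seed=seed,
    )
    model = train_cvae(volumes, covariates, dementia, cvae_cfg)
    latents = encode_volumes(model, volumes)
    k = min(fp.n_pcs, latents.features.shape[1], latents.features.shape[0] - 1)
    pcmodel, scores = fit_pca(latents, k)
    state.update(cvae=model, latents=latents, pcmodel=pcmodel, scores=scores)

    paths = []
    model.save(out / "cvae_model.npz")
    paths.append(out / "cvae_model.npz")
    paths.append(lgio.write_latents(latents, out / "latents.tsv"))
    score_df = pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(scores.shape[1])])
    score_df.insert(0, "sample_id", latents.sample_ids)
    score_df.to_csv(out / "pc_scores.tsv", sep="\t", index=False, float_format="%.12g")
    paths.append(out / "pc_scores.tsv")
    pcmodel.save(out / "pca_model.npz")
    paths.append(out / "pca_model.npz")
    evr = pd.DataFrame(
        {"pc": np.arange(1, k + 1), "explained_variance_ratio": pcmodel.explained_variance_ratio}
    )
    evr.to_csv(out / "explained_variance.tsv", sep="\t", index=False, float_format="%.12g")
    paths.append(out / "explained_variance.tsv")
    hist = pd.DataFrame(model.history)
    hist.to_csv(out / "training_history.tsv", sep="\t", index=False, float_format="%.12g")
    paths.append(out / "training_history.tsv")
    return paths


def _load_scores(state: dict, out: Path) -> pd.DataFrame:
    if "scores" in state:
        df = pd.DataFrame(
            state["scores"], columns=[f"PC{j + 1}" for j in range(state["scores"].shape[1])]
        )
        return df
    df = pd.read_csv(out / "pc_scores.tsv", sep="\t")
    return df.drop(columns="sample_id")


def _stage_gwas(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    gp = config.gwas
    panel = _require(state, out, "panel")
    covariates = _require(state, out, "covariates")
    dementia = _require(state, out, "dementia")
    scores = _load_scores(state, out)

    qc_panel, report = gwas.qc_filter(
        panel, maf_min=gp.maf_min, hwe_alpha=gp.hwe_alpha, miss_max=gp.miss_max,
        prune_r2=gp.prune_r2, prune_window_bp=gp.prune_window_bp,
    )
    state["qc_panel"] = qc_panel
    keep = [s for s in qc_panel.sample_ids]
    cov = covariates.align(keep)
    idx = [panel.sample_ids.index(s) for s in keep]
    traits = scores.to_numpy(float)[idx]
    sd = traits.std(axis=0)
    traits = (traits - traits.mean(axis=0)) / np.where(sd == 0, 1.0, sd)  # unit-variance traits
    names = list(scores.columns)
    stats_list = gwas.association_scan(qc_panel, traits, cov, trait_names=names)
    dem_stats = gwas.association_scan(
        qc_panel, (np.asarray(dementia)[idx] - np.mean(dementia)) / np.std(dementia),
        cov, trait_names=["dementia"],
    )[0]
    state["stats_list"] = stats_list
    state["dem_stats"] = dem_stats

    paths = []
    with open(out / "qc_report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    paths.append(out / "qc_report.json")
    loci_all = []
    for ss in stats_list:
        paths.append(lgio.write_sumstats(ss, out / f"sumstats_{ss.trait}.tsv"))
        loci_all.append(gwas.clump(ss, window_bp=gp.clump_window_bp,
                                   index_p=gp.index_p, member_p=gp.member_p))
    paths.append(lgio.write_sumstats(dem_stats, out / "sumstats_dementia.tsv"))
    agg = gwas.aggregate_traits(stats_list)
    paths.append(lgio.write_sumstats(agg, out / "sumstats_aggregated.tsv"))
    agg_loci = gwas.clump(agg, window_bp=gp.clump_window_bp,
                          index_p=gp.index_p, member_p=gp.member_p)
    state["agg_loci"] = agg_loci
    paths.append(lgio.write_loci(agg_loci, out / "loci_aggregated.tsv"))
    rows = [lt.table for lt in loci_all if len(lt)]
    per_trait = pd.concat(rows, ignore_index=True) if rows else gwas.LocusTable.empty().table
    per_trait.to_csv(out / "loci_per_trait.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "loci_per_trait.tsv")
    return paths


def _stage_interpret(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    volumes = _require(state, out, "volumes")
    covariates = _require(state, out, "covariates")
    scores = _load_scores(state, out)
    if "phenobank" in state:
        bank, types = state["phenobank"]
    else:
        bank = pd.read_csv(out / "phenobank.tsv", sep="\t", index_col=0)
        with open(out / "phenotypes.types.json") as fh:
            types = json.load(fh)

    pc1 = scores.iloc[:, 0].to_numpy(float)
    phewas = interpret.phewas_scan(
        pc1, bank, types, covariates.table[["age", "sex"]], n_traits=scores.shape[1]
    )
    spm = interpret.voxel_spm(volumes, pc1)
    frac = interpret.roi_fraction(spm, volumes.roi_labels)
    varexp = interpret.roi_variance_explained(volumes, pc1)

    paths = []
    phewas.to_csv(out / "phewas_pc1.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "phewas_pc1.tsv")
    import nibabel as nib

    affine = np.diag([*volumes.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(spm.t.astype(np.float32), affine), out / "spm_pc1.nii")
    paths.append(out / "spm_pc1.nii")
    roi_df = pd.DataFrame(
        {
            "roi": sorted(frac),
            "significant_fraction": [frac[r] for r in sorted(frac)],
            "variance_explained": [varexp[r] for r in sorted(frac)],
        }
    )
    roi_df.to_csv(out / "roi_summary_pc1.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "roi_summary_pc1.tsv")
    return paths


def _stage_pgs(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    pp = config.pgs
    panel = state.get("qc_panel") or _require(state, out, "panel")
    covariates = _require(state, out, "covariates")
    dementia = np.asarray(_require(state, out, "dementia"))
    if "dem_stats" in state:
        dem_stats = state["dem_stats"]
        stats_list = state["stats_list"]
    else:
        dem_stats = lgio.read_sumstats(out / "sumstats_dementia.tsv", trait="dementia")
        stats_list = []  # standalone rerun: PC stats optional
    orig_ids = state["panel"].sample_ids if "panel" in state else panel.sample_ids
    pos = {s: i for i, s in enumerate(orig_ids)}
    y = dementia[[pos[s] for s in panel.sample_ids]]

    rng = np.random.default_rng(seed)
    w_dem = pgsmod.fit_ct_pgs(dem_stats, panel, y, p_thresholds=pp.p_thresholds,
                              seed=int(rng.integers(2**31)))
    base = pgsmod.score(panel, w_dem)
    extra_cols = []
    for ss in stats_list:
        w = pgsmod.fit_ct_pgs(ss, p_thresholds=pp.p_thresholds)
        if len(w):
            extra_cols.append(pgsmod.score(panel, w))
    extra = np.column_stack(extra_cols) if extra_cols else rng.standard_normal((panel.n_samples, 1))
    cov = covariates.align(panel.sample_ids)
    C = np.column_stack([cov.table["age"].to_numpy(float), cov.table["sex"].to_numpy(float)])
    result = pgsmod.multi_pgs_eval(
        y, base, extra, covariates=C, train_frac=pp.train_frac,
        seed=int(rng.integers(2**31)), n_perm=pp.n_perm,
    )

    paths = [lgio.write_weights(w_dem, out / "pgs_weights_dementia.tsv")]
    report = pd.DataFrame(
        [{
            "trait": "dementia_score",
            "r2_base": result.r2_base,
            "r2_extended": result.r2_extended,
            "delta": result.delta,
            "perm_p": result.perm_p,
            "n_train": result.n_train,
            "n_test": result.n_test,
        }]
    )
    report.to_csv(out / "multi_pgs_eval.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "multi_pgs_eval.tsv")
    return paths


def _stage_gencorr(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[Path]:
    gp = config.gencorr
    panel = state.get("qc_panel") or _require(state, out, "panel")
    if "stats_list" in state and len(state["stats_list"]) >= 2:
        s1, s2 = state["stats_list"][0], state["stats_list"][1]
        focal = state["dem_stats"]
    else:
        s1 = lgio.read_sumstats(out / "sumstats_PC1.tsv", trait="PC1")
        s2 = lgio.read_sumstats(out / "sumstats_PC2.tsv", trait="PC2")
        focal = lgio.read_sumstats(out / "sumstats_dementia.tsv", trait="dementia")

    ld = gencorr.ld_scores(panel, window_bp=gp.ld_window_bp)
    fit1 = gencorr.ldsc_h2(s1, ld)
    fit2 = gencorr.ldsc_h2(s2, ld)
    rg = gencorr.ldsc_rg(s1, s2, ld)
    regions = gencorr.shared_regions(
        focal, s1, s2, p_max=gp.shared_p_max, zprod_min=gp.shared_zprod_min,
        rg_signs=(None, None),
    )

    paths = []
    ld.to_csv(out / "ld_scores.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "ld_scores.tsv")
    fits = pd.DataFrame(
        [
            {"trait": s1.trait, "h2": fit1.h2, "h2_se": fit1.h2_se, "intercept": fit1.intercept},
            {"trait": s2.trait, "h2": fit2.h2, "h2_se": fit2.h2_se, "intercept": fit2.intercept},
        ]
    )
    fits.to_csv(out / "ldsc_h2.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "ldsc_h2.tsv")
    rg_df = pd.DataFrame(
        [{
            "trait1": s1.trait, "trait2": s2.trait, "rg": rg.rg, "rg_se": rg.rg_se,
            "gencov": rg.gencov, "flag": rg.flagged or "",
        }]
    )
    rg_df.to_csv(out / "ldsc_rg.tsv", sep="\t", index=False, float_format="%.10g")
    paths.append(out / "ldsc_rg.tsv")
    with open(out / "shared_regions.json", "w") as fh:
        json.dump(regions, fh, indent=2)
    paths.append(out / "shared_regions.json")
    return paths
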