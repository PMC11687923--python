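"""Phenome-wide scans of learned traits, voxel-wise statistical parametric
maps, and per-ROI summaries (significantly-correlated-voxel fractions and
variance-explained ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .gwas import bonferroni_threshold
from .types import VolumeStack

__all__ = [
    "SPMap",
    "phewas_scan",
    "rank_inverse_normal",
    "voxel_spm",
    "roi_fraction",
    "roi_variance_explained",
]


@dataclass
class SPMap:
    """Voxel-wise t-statistic map with its Bonferroni significance mask."""

    t: np.ndarray                  # volume-shaped; 0 outside the brain mask
    threshold: float               # |t| cutoff (Bonferroni over tested voxels)
    significant: np.ndarray        # boolean, |t| >= threshold within the mask
    mask: np.ndarray               # voxels actually tested
    n: int                         # samples used
    n_voxels_tested: int
    n_flagged_constant: int = 0


def rank_inverse_normal(x: np.ndarray, c: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform (ties get average ranks)."""
    x = np.asarray(x, float)
    ranks = sps.rankdata(x)
    return sps.norm.ppf((ranks - c) / (len(x) - 2 * c + 1))


def phewas_scan(
    scores: np.ndarray,
    phenobank: pd.DataFrame,
    types: dict[str, str],
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_traits: int = 1,
    alpha: float = 0.05,
    transform: str = "int",
) -> pd.DataFrame:
    """Scan one learned trait against a bank of phenotypes.

    Continuous phenotypes are rank-inverse-normal transformed (unless
    ``transform="none"``) and fit by least squares; binary phenotypes by
    logistic regression. Age and sex covariates are always included when
    supplied. The Bonferroni threshold reported alongside accounts for
    ``n_traits * n_phenotypes`` tests. Binary phenotypes with a single
    observed class are flagged untestable rather than raising.

    Returns a DataFrame with one row per phenotype: model, effect size
    (score coefficient), p, significance flag, and the threshold used.
    """
    if transform not in ("int", "none"):
        raise ValueError("transform must be 'int' or 'none'")
    s = np.asarray(scores, float)
    n = len(s)
    if covariates is None:
        C = np.empty((n, 0))
    elif isinstance(covariates, pd.DataFrame):
        cols = [c for c in ("age", "sex") if c in covariates.columns] or list(covariates.columns)
        C = covariates[cols].to_numpy(float)
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
    X = sm.add_constant(np.column_stack([s, C]) if C.size else s[:, None], has_constant="add")

    threshold = bonferroni_threshold(alpha, n_traits * phenobank.shape[1])
    rows = []
    for name in phenobank.columns:
        y = phenobank[name].to_numpy(float)
        kind = types[name]
        row = {"phenotype": name, "model": None, "beta": np.nan, "p": np.nan,
               "significant": False, "flag": "", "threshold": threshold}
        if kind == "continuous":
            yt = rank_inverse_normal(y) if transform == "int" else y
            fit = sm.OLS(yt, X).fit()
            row.update(model="linear", beta=float(fit.params[1]), p=float(max(fit.pvalues[1], 5e-324)))
        elif kind == "binary":
            classes = np.unique(y)
            if len(classes) < 2:
                row.update(model="logistic", flag="untestable: single class")
                rows.append(row)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                    row.update(
                        model="logistic",
                        beta=float(fit.params[1]),
                        p=float(max(fit.pvalues[1], 5e-324)),
                    )
                except Exception as exc:  # separation etc.
                    row.update(model="logistic", flag=f"fit failed: {type(exc).__name__}")
        else:
            raise ValueError(f"unknown phenotype type {kind!r} for {name!r}")
        if np.isfinite(row["p"]):
            row["significant"] = bool(row["p"] < threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def voxel_spm(
    volumes: VolumeStack,
    variable: np.ndarray,
    brain_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> SPMap:
    """Per-voxel Pearson correlation with a variable, as a t-statistic map.

    t = r sqrt((n-2)/(1-r^2)); the significance threshold is the two-sided
    t quantile at alpha Bonferroni-corrected for the number of in-mask
    voxels. Constant voxels get t = 0 by convention and are counted.
    """
    v = np.asarray(variable, float)
    n = volumes.n_samples
    if len(v) != n:
        raise ValueError("variable length differs from the number of volumes")
    if v.std() == 0:
        raise ValueError("variable must vary across samples")
    mask = np.ones(volumes.shape, bool) if brain_mask is None else np.asarray(brain_mask, bool)
    if mask.shape != volumes.shape:
        raise ValueError("brain mask shape differs from volume shape")
    if not mask.any():
        raise ValueError("brain mask is empty")

    X = volumes.volumes.reshape(n, -1)[:, mask.ravel()].astype(float)
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sv = np.sqrt(vc @ vc)
    const = sx == 0
    sx_safe = np.where(const, 1.0, sx)
    r = (Xc.T @ vc) / (sx_safe * sv)
    r = np.clip(np.where(const, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))

    n_vox = int(mask.sum())
    thr = float(sps.t.isf(bonferroni_threshold(alpha, n_vox) / 2.0, df=n - 2))
    t_map = np.zeros(volumes.shape)
    t_map[mask] = t
    sig = np.zeros(volumes.shape, bool)
    sig[mask] = np.abs(t) >= thr
    return SPMap(
        t=t_map, threshold=thr, significant=sig, mask=mask, n=n,
        n_voxels_tested=n_vox, n_flagged_constant=int(const.sum()),
    )


def roi_fraction(spm: SPMap, roi_labels: np.ndarray) -> dict[int, float]:
    """Per ROI: significant in-mask voxels divided by ROI voxel count."""
    roi_labels = np.asarray(roi_labels, int)
    out = {}
    for lab in np.unique(roi_labels):
        if lab == 0:
            continue
        roi = roi_labels == lab
        out[int(lab)] = float(np.logical_and(spm.significant, roi).sum() / roi.sum())
    return out


def roi_variance_explained(
    volumes: VolumeStack,
    variable: np.ndarray,
    roi_labels: np.ndarray | None = None,
) -> dict[int, float]:
    """Variance-weighted per-voxel R^2 with the variable, aggregated per ROI.

    For ROI voxels v with across-sample variance Var_v and squared Pearson
    correlation r^2_v: ratio = sum_v r^2_v Var_v / sum_v Var_v. Always in
    [0, 1]; 1 when every ROI voxel is an exact affine function of the
    variable, ~0 for pure noise.
    """
    labels = np.asarray(volumes.roi_labels if roi_labels is None else roi_labels, int)
    v = np.asarray(variable, float)
    n = volumes.n_samples
    X = volumes.volumes.reshape(n, -1).astype(float)
    Xc = X - X.mean(axis=0)
    var = np.einsum("ij,ij->j", Xc, Xc) / n
    vc = v - v.mean()
    sv2 = vc @ vc
    cov = (Xc.T @ vc) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var > 0, cov**2 / (var * (sv2 / n)), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    flat_labels = labels.ravel()
    out = {}
    for lab in np.unique(flat_labels):
        if lab == 0:
            continue
        sel = flat_labels == lab
        denom = var[sel].sum()
        out[int(lab)] = float((r2[sel] * var[sel]).sum() / denom) if denom > 0 else 0.0
    return out
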