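"""LD scores, LD-score-regression heritability and genetic correlation,
and the shared-region z-product screen.

The regression follows the standard expectation model

    E[chi^2_j]   = 1 + N h^2 l_j / M
    E[z1_j z2_j] = intercept + sqrt(N1 N2) rho_g l_j / M

fit by weighted least squares with a free intercept. Weighting is a
documented two-step scheme (first pass 1/l, second pass the inverse of the
model-implied variance of the response); standard errors come from a
delete-one block jackknife over contiguous position-ordered variant blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypePanel, SummaryStats

__all__ = ["ld_scores", "ldsc_h2", "ldsc_rg", "shared_regions", "LdscFit"]

_RG_CLIP = 1.25


@dataclass
class LdscFit:
    """Result of an LD-score regression fit."""

    h2: float | None = None
    h2_se: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    rg_raw: float | None = None
    gencov: float | None = None
    cross_intercept: float | None = None
    h2_pair: tuple[float, float] | None = None
    M: int = 0
    N: float | tuple[float, float] = 0
    n_blocks: int = 0
    flagged: str | None = None


def ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-variant LD score: windowed sum of bias-adjusted squared r.

    l_j = sum over variants k with |pos_k - pos_j| <= window on the same
    chromosome of r~^2_jk, where r~^2 = r^2 - (1 - r^2)/(n - 2) corrects the
    upward sampling bias of r^2 (the self-term contributes exactly 1).
    Monomorphic variants are excluded with a warning.
    """
    n = panel.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for adjusted LD scores")
    G = panel.dosages_imputed()
    sd = G.std(axis=0)
    poly = sd > 0
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variants from LD scores")
    idx = np.flatnonzero(poly)
    Gs = (G[:, idx] - G[:, idx].mean(axis=0)) / sd[idx]
    chrom = panel.variants["chrom"].astype(str).to_numpy()[idx]
    pos = panel.variants["pos"].to_numpy()[idx]
    m = len(idx)
    ell = np.empty(m)
    lo = 0
    for j in range(m):
        while lo < j and (chrom[lo] != chrom[j] or pos[j] - pos[lo] > window_bp):
            lo += 1
        hi = j
        while hi + 1 < m and chrom[hi + 1] == chrom[j] and pos[hi + 1] - pos[j] <= window_bp:
            hi += 1
        r = (Gs[:, lo : hi + 1].T @ Gs[:, j]) / n
        r2 = r**2
        ell[j] = float(np.sum(r2 - (1.0 - r2) / (n - 2)))
    return pd.DataFrame(
        {
            "id": panel.variants["id"].to_numpy()[idx],
            "chrom": chrom,
            "pos": pos,
            "ld_score": ell,
        }
    )


def _merge_on_ld(stats: SummaryStats, ld: pd.DataFrame) -> pd.DataFrame:
    t = stats.table[["ID", "CHR", "POS", "Z", "N"]].rename(columns={"ID": "id"})
    merged = t.merge(ld[["id", "ld_score"]], on="id", how="inner")
    merged = merged.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return merged


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return float(coef[1]), float(coef[0])


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    mean = values.mean()
    return float(np.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))


def _h2_fit(ell: np.ndarray, chi2: np.ndarray, N: float, M: int) -> tuple[float, float]:
    """Two-step weighted chi^2-on-l regression; returns (h2, intercept)."""
    w0 = 1.0 / np.maximum(ell, 1.0)
    slope0, _ = _wls(ell, chi2, w0)
    h2_0 = np.clip(slope0 * M / N, 0.0, 1.0)
    fitted_var = 2.0 * (1.0 + N * h2_0 * ell / M) ** 2
    w = 1.0 / (np.maximum(ell, 1.0) * fitted_var)
    slope, intercept = _wls(ell, chi2, w)
    return slope * M / N, intercept


def ldsc_h2(
    stats: SummaryStats,
    ld: pd.DataFrame,
    M: int | None = None,
    n_blocks: int = 20,
) -> LdscFit:
    """Heritability by LD-score regression with block-jackknife s.e."""
    merged = _merge_on_ld(stats, ld)
    if len(merged) < 50:
        raise ValueError(f"only {len(merged)} variants with LD scores; need >= 50")
    M = int(M) if M is not None else len(ld)
    N = float(merged["N"].median())
    ell = merged["ld_score"].to_numpy(float)
    chi2 = merged["Z"].to_numpy(float) ** 2

    h2, intercept = _h2_fit(ell, chi2, N, M)
    blocks = np.array_split(np.arange(len(merged)), n_blocks)
    pseudo_h2, pseudo_int = [], []
    for b in blocks:
        mask = np.ones(len(merged), dtype=bool)
        mask[b] = False
        ph, pi = _h2_fit(ell[mask], chi2[mask], N, M)
        pseudo_h2.append(ph)
        pseudo_int.append(pi)
    return LdscFit(
        h2=float(h2),
        h2_se=max(_jackknife(np.asarray(pseudo_h2)), 1e-12),
        intercept=float(intercept),
        intercept_se=max(_jackknife(np.asarray(pseudo_int)), 1e-12),
        M=M, N=N, n_blocks=n_blocks,
    )


def _rg_fit(
    ell: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    N1: float,
    N2: float,
    M: int,
) -> tuple[float, float, float, float, float]:
    """Returns (rg_raw, gencov, cross_intercept, h2_1, h2_2) on one subset."""
    h2_1, _ = _h2_fit(ell, z1**2, N1, M)
    h2_2, _ = _h2_fit(ell, z2**2, N2, M)
    y = z1 * z2
    w0 = 1.0 / np.maximum(ell, 1.0)
    slope0, _ = _wls(ell, y, w0)
    h1c, h2c = np.clip(h2_1, 0.0, 1.0), np.clip(h2_2, 0.0, 1.0)
    v1 = 1.0 + N1 * h1c * ell / M
    v2 = 1.0 + N2 * h2c * ell / M
    cross = (slope0 * ell) ** 2
    w = 1.0 / (np.maximum(ell, 1.0) * (v1 * v2 + cross))
    slope, intercept = _wls(ell, y, w)
    gencov = slope * M / np.sqrt(N1 * N2)
    if h2_1 <= 0 or h2_2 <= 0:
        return np.nan, gencov, intercept, h2_1, h2_2
    return gencov / np.sqrt(h2_1 * h2_2), gencov, intercept, h2_1, h2_2


def ldsc_rg(
    stats1: SummaryStats,
    stats2: SummaryStats,
    ld: pd.DataFrame,
    M: int | None = None,
    n_blocks: int = 20,
) -> LdscFit:
    """Cross-trait genetic correlation by LD-score regression.

    Regresses z1*z2 on l with a free intercept (which absorbs sample
    overlap); genetic covariance = slope * M / sqrt(N1 N2) and
    rg = gencov / sqrt(h2_1 h2_2) with each h2 from :func:`ldsc_h2`'s
    estimator on the shared variant set. The reported rg is clipped to
    [-1.25, 1.25]; the raw value is kept in ``rg_raw``. If either h2
    estimate is <= 0 the rg is undefined and flagged.
    """
    m1 = _merge_on_ld(stats1, ld).rename(columns={"Z": "Z1", "N": "N1"})
    m2 = stats2.table[["ID", "Z", "N"]].rename(columns={"ID": "id", "Z": "Z2", "N": "N2"})
    merged = m1.merge(m2, on="id", how="inner")
    if len(merged) < 50:
        raise ValueError(f"only {len(merged)} shared variants with LD scores; need >= 50")
    M = int(M) if M is not None else len(ld)
    N1 = float(merged["N1"].median())
    N2 = float(merged["N2"].median())
    ell = merged["ld_score"].to_numpy(float)
    z1 = merged["Z1"].to_numpy(float)
    z2 = merged["Z2"].to_numpy(float)

    rg_raw, gencov, intercept, h2_1, h2_2 = _rg_fit(ell, z1, z2, N1, N2, M)
    blocks = np.array_split(np.arange(len(merged)), n_blocks)
    pseudo = []
    for b in blocks:
        mask = np.ones(len(merged), dtype=bool)
        mask[b] = False
        pseudo.append(_rg_fit(ell[mask], z1[mask], z2[mask], N1, N2, M)[0])
    pseudo = np.asarray(pseudo)
    se = _jackknife(pseudo[np.isfinite(pseudo)]) if np.isfinite(pseudo).all() else np.nan

    flagged = None
    if not np.isfinite(rg_raw):
        flagged = "h2 estimate <= 0: rg undefined"
        rg = None
    else:
        rg = float(np.clip(rg_raw, -_RG_CLIP, _RG_CLIP))
    return LdscFit(
        rg=rg,
        rg_se=float(max(se, 1e-12)) if np.isfinite(se) else None,
        rg_raw=float(rg_raw) if np.isfinite(rg_raw) else None,
        gencov=float(gencov),
        cross_intercept=float(intercept),
        h2_pair=(float(h2_1), float(h2_2)),
        M=M,
        N=(N1, N2),
        n_blocks=n_blocks,
        flagged=flagged,
    )


def shared_regions(
    focal: SummaryStats,
    trait_b: SummaryStats,
    trait_c: SummaryStats,
    p_max: float = 1e-4,
    zprod_min: float = 15.0,
    window_bp: int = 250_000,
    rg_signs: tuple[int | None, int | None] = (None, 1),
) -> list[dict]:
    """Regions whose variants drive two genetic correlations at once.

    Candidate variants satisfy: focal p < ``p_max``, |z_focal*z_b| >
    ``zprod_min``, |z_focal*z_c| > ``zprod_min``, and — for each entry of
    ``rg_signs`` that is not None — sign(z_focal*z_x) equal to that sign.
    Candidates are grouped greedily: the one with the largest
    |z_focal*z_b| becomes a central variant absorbing all candidates within
    +/- ``window_bp`` on its chromosome; repeat until none remain.
    """
    f = focal.table[["ID", "CHR", "POS", "Z", "P"]].rename(columns={"Z": "ZF", "P": "PF"})
    b = trait_b.table[["ID", "Z"]].rename(columns={"Z": "ZB"})
    c = trait_c.table[["ID", "Z"]].rename(columns={"Z": "ZC"})
    merged = f.merge(b, on="ID", how="inner").merge(c, on="ID", how="inner")
    if merged.empty:
        raise ValueError("the three summary-statistics tables share no variants")

    zb = merged["ZF"].to_numpy() * merged["ZB"].to_numpy()
    zc = merged["ZF"].to_numpy() * merged["ZC"].to_numpy()
    mask = (
        (merged["PF"].to_numpy() < p_max)
        & (np.abs(zb) > zprod_min)
        & (np.abs(zc) > zprod_min)
    )
    sign_b, sign_c = rg_signs
    if sign_b is not None:
        mask &= np.sign(zb) == np.sign(sign_b)
    if sign_c is not None:
        mask &= np.sign(zc) == np.sign(sign_c)

    cand = merged.loc[mask].reset_index(drop=True)
    cand = cand.assign(ZPROD_B=zb[mask], ZPROD_C=zc[mask])
    regions: list[dict] = []
    remaining = cand.copy()
    while not remaining.empty:
        central = remaining.loc[remaining["ZPROD_B"].abs().idxmax()]
        near = remaining[
            (remaining["CHR"].astype(str) == str(central["CHR"]))
            & ((remaining["POS"] - central["POS"]).abs() <= window_bp)
        ]
        regions.append(
            {
                "central_id": central["ID"],
                "chrom": str(central["CHR"]),
                "pos": int(central["POS"]),
                "members": list(near["ID"]),
                "zprod_b": float(central["ZPROD_B"]),
                "zprod_c": float(central["ZPROD_C"]),
            }
        )
        remaining = remaining.drop(near.index)
    return regions
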