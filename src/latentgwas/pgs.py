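"""Polygenic scores by clumping + thresholding, cohort scoring with allele
matching, nested multi-PGS evaluation on a train/test split, and the
prediction-swap permutation test on the test-set R^2 difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import clump
from .types import GenotypePanel, SummaryStats

__all__ = [
    "PGSWeights",
    "MultiPgsEval",
    "fit_ct_pgs",
    "score",
    "multi_pgs_eval",
    "permutation_test_r2",
]

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PGSWeights:
    """Per-variant effect-allele weights (trait-SD units per allele)."""

    table: pd.DataFrame  # columns: ID, EA, OA, WEIGHT
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"ID", "EA", "OA", "WEIGHT"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"weights lack columns {required - set(self.table.columns)}")
        if self.table["ID"].duplicated().any():
            raise ValueError("duplicated variant ids in PGS weights")
        if not np.isfinite(self.table["WEIGHT"].to_numpy(float)).all():
            raise ValueError("PGS weights must be finite")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MultiPgsEval:
    """Nested-model comparison on one train/test split."""

    r2_base: float
    r2_extended: float
    delta: float
    perm_p: float | None
    n_train: int
    n_test: int


def fit_ct_pgs(
    stats: SummaryStats,
    panel: GenotypePanel | None = None,
    y: np.ndarray | None = None,
    p_thresholds: tuple[float, ...] = (5e-8, 1e-6, 1e-4, 1e-2),
    window_bp: int = 250_000,
    val_frac: float = 0.3,
    seed: int = 0,
) -> PGSWeights:
    """Clumping + thresholding PGS with validation-fold threshold selection.

    For each p threshold the summary statistics are distance-clumped at
    that threshold and the index variants keep their marginal betas as
    weights. When a tuning cohort (``panel`` + ``y``) is supplied, a
    held-out fold of it (``val_frac``) picks the threshold with the best
    validation R^2; otherwise the most stringent non-empty threshold wins.
    Returns empty weights (with a warning) if nothing passes any threshold.
    """
    candidates: dict[float, PGSWeights] = {}
    for thr in sorted(p_thresholds):
        loci = clump(stats, window_bp=window_bp, index_p=thr, member_p=thr)
        if len(loci) == 0:
            continue
        sub = stats.table.set_index("ID").loc[loci.table["index_id"]]
        table = pd.DataFrame(
            {
                "ID": sub.index.to_numpy(),
                "EA": sub["A1"].to_numpy(),
                "OA": sub["A2"].to_numpy(),
                "WEIGHT": sub["BETA"].to_numpy(float),
            }
        )
        candidates[thr] = PGSWeights(
            table, provenance={"p_threshold": thr, "window_bp": window_bp, "method": "C+T"}
        )

    if not candidates:
        logger.warning("no variant passed any p threshold; returning empty PGS")
        return PGSWeights(
            pd.DataFrame(columns=["ID", "EA", "OA", "WEIGHT"]),
            provenance={"p_threshold": None, "window_bp": window_bp, "method": "C+T"},
        )

    if panel is None or y is None:
        best = min(candidates)  # most stringent threshold that yields weights
        return candidates[best]

    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    val = rng.permutation(panel.n_samples)[: max(2, int(round(val_frac * panel.n_samples)))]
    panel_val = panel.subset(sample_idx=val)
    y_val = y[val]
    best_thr, best_r2 = None, -np.inf
    for thr, w in candidates.items():
        s = score(panel_val, w)
        if s.std() == 0:
            continue
        r = np.corrcoef(s, y_val)[0, 1]
        if r**2 > best_r2:
            best_thr, best_r2 = thr, r**2
    if best_thr is None:
        best_thr = min(candidates)
    chosen = candidates[best_thr]
    chosen.provenance["validation_r2"] = float(best_r2) if np.isfinite(best_r2) else None
    return chosen


def score(panel: GenotypePanel, weights: PGSWeights) -> np.ndarray:
    """Weighted sum of effect-allele dosages, with allele-flip matching.

    If a weight's effect allele matches the panel's ref (and its other
    allele the panel's alt), the dosage is flipped to ``2 - d``. Variants
    absent from the panel or with incompatible alleles are skipped and
    counted in the log. Strand-ambiguous (A/T, C/G) variants are scored
    as-is with a warning. Missing dosages are mean-imputed.
    """
    if len(weights) == 0:
        return np.zeros(panel.n_samples)
    vmap = panel.variants.reset_index().set_index("id")
    D = panel.dosages_imputed()
    total = np.zeros(panel.n_samples)
    skipped = ambiguous = 0
    for row in weights.table.itertuples(index=False):
        if row.ID not in vmap.index:
            skipped += 1
            continue
        v = vmap.loc[row.ID]
        col = int(v["index"])
        ea, oa = str(row.EA), str(row.OA)
        if (ea, oa) in _AMBIGUOUS:
            ambiguous += 1
        if ea == v["alt"] and oa == v["ref"]:
            d = D[:, col]
        elif ea == v["ref"] and oa == v["alt"]:
            d = 2.0 - D[:, col]
        else:
            skipped += 1
            continue
        total += float(row.WEIGHT) * d
    if skipped:
        logger.info("PGS scoring skipped %d unmatched variants", skipped)
    if ambiguous:
        logger.warning("scored %d strand-ambiguous (A/T or C/G) variants as-is", ambiguous)
    return total


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum((y - pred) ** 2) / ss_tot)


def _fit_predict(y_tr, X_tr, X_te) -> tuple[np.ndarray, np.ndarray]:
    coef, *_ = np.linalg.lstsq(X_tr, y_tr, rcond=None)
    return X_tr @ coef, X_te @ coef


def multi_pgs_eval(
    y: np.ndarray,
    base_scores: np.ndarray,
    extra_scores: np.ndarray,
    covariates: np.ndarray | None = None,
    train_frac: float = 0.6,
    seed: int = 0,
    n_perm: int = 0,
) -> MultiPgsEval:
    """Compare nested linear predictors on a random train/test split.

    The base model regresses the trait on covariates + base (trait-specific)
    PGS; the extended model adds the extra PGS columns. Both are fit on the
    training split only and scored by R^2 on the held-out split. With
    ``n_perm > 0`` the prediction-swap permutation test supplies a p-value
    for the R^2 difference.
    """
    y = np.asarray(y, float)
    base_scores = np.atleast_2d(np.asarray(base_scores, float))
    extra_scores = np.atleast_2d(np.asarray(extra_scores, float))
    if base_scores.shape[0] != len(y):
        base_scores = base_scores.T
    if extra_scores.shape[0] != len(y):
        extra_scores = extra_scores.T
    n = len(y)
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("degenerate train/test split")
    tr, te = perm[:n_train], perm[n_train:]

    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov.size and cov.shape[0] != n:
        cov = cov.T
    ones = np.ones((n, 1))
    X_base = np.hstack([ones, cov, base_scores])
    X_ext = np.hstack([X_base, extra_scores])

    _, pred_base = _fit_predict(y[tr], X_base[tr], X_base[te])
    _, pred_ext = _fit_predict(y[tr], X_ext[tr], X_ext[te])
    r2_base = _r2(y[te], pred_base)
    r2_ext = _r2(y[te], pred_ext)

    perm_p = None
    if n_perm > 0:
        perm_p = permutation_test_r2(y[te], pred_base, pred_ext, n_perm=n_perm, seed=seed)
    return MultiPgsEval(
        r2_base=r2_base,
        r2_extended=r2_ext,
        delta=r2_ext - r2_base,
        perm_p=perm_p,
        n_train=n_train,
        n_test=n - n_train,
    )


def permutation_test_r2(
    y_test: np.ndarray,
    pred_base: np.ndarray,
    pred_ext: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Prediction-swap permutation p-value for an R^2 difference.

    Observed statistic: R^2(extended) - R^2(base) on the test set. Each
    permutation assigns, per test sample by a fair coin, one model's
    prediction to hybrid A and the other's to hybrid B, and records the
    hybrid R^2 difference. Two-sided with add-one correction:
    p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm), so p >= 1/(n_perm+1)
    and p = 1 when the two prediction vectors are identical.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y_test, float)
    a = np.asarray(pred_ext, float)
    b = np.asarray(pred_base, float)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y and predictions must share length")
    d_obs = _r2(y, a) - _r2(y, b)

    rng = np.random.default_rng(seed)
    coin = rng.random((n_perm, len(y))) < 0.5
    hyb_a = np.where(coin, a[None, :], b[None, :])
    hyb_b = np.where(coin, b[None, :], a[None, :])
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    res_a = np.sum((y[None, :] - hyb_a) ** 2, axis=1)
    res_b = np.sum((y[None, :] - hyb_b) ** 2, axis=1)
    d_perm = (res_b - res_a) / ss_tot  # R2(A) - R2(B)
    n_extreme = int(np.sum(np.abs(d_perm) >= np.abs(d_obs) - 1e-15))
    return float((1 + n_extreme) / (1 + n_perm))
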