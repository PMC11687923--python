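"""SNP quality control, covariate-adjusted association scans, multiple-testing
thresholds, distance-based clumping, cross-trait aggregation, and the
discovery/replication split.

The association model is ordinary least squares of each trait on one variant
dosage at a time plus the full covariate design (intercept, age, sex, batch
dummies, genetic PCs). Population structure is controlled through the
genotype-PC covariates rather than a mixed model; residualizing both the
trait and the dosages on the covariates (Frisch-Waugh) makes the scan a
single matrix product per trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    CovariateTable,
    GenotypePanel,
    LocusTable,
    QCReport,
    SummaryStats,
    summary_stats_from_arrays,
)

__all__ = [
    "hwe_test",
    "qc_filter",
    "association_scan",
    "bonferroni_threshold",
    "clump",
    "aggregate_traits",
    "merge_loci",
    "replicate_split",
]


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df Pearson chi-square).

    Expected genotype counts come from the sample allele frequency; the
    statistic has one degree of freedom (three classes, one estimated
    frequency). Returns 1.0 for exact HWE proportions.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    if (expected == 0).any():  # monomorphic: observed == expected, no test
        return 1.0
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(max(sps.chi2.sf(chi2, df=1), 5e-324))


def _genotype_counts(dosages_col: np.ndarray) -> tuple[int, int, int]:
    """Round non-missing dosages to hard calls and tally genotype classes."""
    from .types import MISSING

    obs = dosages_col[dosages_col != MISSING]
    g = np.clip(np.rint(obs), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.001,
    hwe_alpha: float = 0.001,
    miss_max: float = 0.1,
    prune_r2: float = 0.8,
    prune_window_bp: int = 500_000,
) -> tuple[GenotypePanel, QCReport]:
    """Variant QC in the order MAF -> missingness -> HWE -> LD-prune.

    Samples with missingness above ``miss_max`` are also dropped (before
    per-variant missingness is computed). LD pruning is windowed greedy
    left-to-right in position order: of any pair within the window with
    r^2 > ``prune_r2``, the later-position variant is dropped.
    """
    input_count = panel.n_variants
    steps: list[tuple[str, int]] = []

    # sample-level missingness first so variant statistics use kept samples
    samp_keep = np.flatnonzero(panel.sample_missingness() <= miss_max)
    samples_removed = panel.n_samples - len(samp_keep)
    if samples_removed:
        panel = panel.subset(sample_idx=samp_keep)

    keep = np.arange(panel.n_variants)

    maf = panel.maf()
    mask = maf >= maf_min
    steps.append(("maf", int((~mask).sum())))
    keep, panel = keep[mask], panel.subset(variant_idx=np.flatnonzero(mask))

    miss = panel.variant_missingness()
    mask = miss <= miss_max
    steps.append(("missingness", int((~mask).sum())))
    keep, panel = keep[mask], panel.subset(variant_idx=np.flatnonzero(mask))

    hwe_p = np.array(
        [hwe_test(*_genotype_counts(panel.dosages[:, j])) for j in range(panel.n_variants)]
    )
    mask = hwe_p >= hwe_alpha
    steps.append(("hwe", int((~mask).sum())))
    keep, panel = keep[mask], panel.subset(variant_idx=np.flatnonzero(mask))

    pruned = _ld_prune(panel, prune_r2, prune_window_bp)
    steps.append(("ld_prune", int(panel.n_variants - len(pruned))))
    panel = panel.subset(variant_idx=pruned)

    report = QCReport(
        steps=steps,
        survivors=panel.n_variants,
        input_count=input_count,
        samples_removed=samples_removed,
    )
    return panel, report


def _ld_prune(panel: GenotypePanel, r2_max: float, window_bp: int) -> np.ndarray:
    """Indices surviving greedy windowed pruning (earlier position kept)."""
    G = panel.dosages_imputed()
    G = G - G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    G = G / sd
    n = G.shape[0]
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants
    dropped = np.zeros(m, dtype=bool)
    for j in range(m):
        if dropped[j]:
            continue
        k = j + 1
        while k < m and chrom[k] == chrom[j] and pos[k] - pos[j] <= window_bp:
            if not dropped[k]:
                r = float(G[:, j] @ G[:, k]) / n
                if r * r > r2_max:
                    dropped[k] = True
            k += 1
    return np.flatnonzero(~dropped)


def bonferroni_threshold(alpha_per_test: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha_per_test <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha_per_test / n_tests


def association_scan(
    panel: GenotypePanel,
    traits: np.ndarray | pd.DataFrame,
    covariates: CovariateTable | None = None,
    trait_names: list[str] | None = None,
) -> list[SummaryStats]:
    """Covariate-adjusted least-squares scan: one SummaryStats per trait.

    For each variant and trait fits ``trait ~ dosage + covariates`` and
    reports the dosage coefficient (beta, se, z = beta/se, two-sided p from
    the t distribution). Missing dosages are mean-imputed per variant;
    variants with zero post-imputation variance get beta = 0, p = 1 and are
    flagged rather than raising.
    """
    if isinstance(traits, pd.DataFrame):
        trait_names = trait_names or [str(c) for c in traits.columns]
        traits = traits.to_numpy(float)
    traits = np.asarray(traits, float)
    if traits.ndim == 1:
        traits = traits[:, None]
    if not np.isfinite(traits).all():
        raise ValueError("traits must be finite")
    n = panel.n_samples
    if traits.shape[0] != n:
        raise ValueError("traits and panel have different sample counts")
    if trait_names is None:
        trait_names = [f"trait{j + 1}" for j in range(traits.shape[1])]

    if covariates is not None:
        if covariates.sample_ids != panel.sample_ids:
            covariates = covariates.align(panel.sample_ids)
        C = covariates.design_matrix()
    else:
        C = np.ones((n, 1))
    Q, _ = np.linalg.qr(C)
    p_cov = np.linalg.matrix_rank(C)

    G = panel.dosages_imputed()
    Gr = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    degenerate = gg < 1e-10 * n
    gg_safe = np.where(degenerate, 1.0, gg)
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")

    maf = panel.maf()
    out = []
    for t_idx, tag in enumerate(trait_names):
        y = traits[:, t_idx]
        yr = y - Q @ (Q.T @ y)
        beta = (Gr.T @ yr) / gg_safe
        rss = np.maximum(yr @ yr - beta**2 * gg_safe, 0.0)
        sigma2 = np.maximum(rss / df, 1e-300)
        se = np.sqrt(sigma2 / gg_safe)
        se = np.where(se <= 0, 1e-150, se)
        z = beta / se
        p = np.clip(2.0 * sps.t.sf(np.abs(z), df=df), 5e-324, 1.0)
        beta = np.where(degenerate, 0.0, beta)
        z = np.where(degenerate, 0.0, z)
        p = np.where(degenerate, 1.0, p)
        se = np.where(degenerate, np.inf, se)
        ss = summary_stats_from_arrays(panel.variants, beta, se, p, n, maf, trait=tag)
        ss.table["ZERO_VAR"] = degenerate.astype(int)
        out.append(ss)
    return out


def clump(
    stats: SummaryStats,
    window_bp: int = 250_000,
    index_p: float = 1e-9,
    member_p: float = 5e-8,
) -> LocusTable:
    """Greedy distance-based clumping into independent loci.

    Repeatedly the unclaimed variant with the smallest p <= ``index_p``
    founds a locus and claims every unclaimed variant with p <= ``member_p``
    within +/- ``window_bp`` on its chromosome. Ties on p break by
    (chrom, pos).
    """
    t = stats.table
    order = np.lexsort((t["POS"].to_numpy(), t["CHR"].astype(str).to_numpy(), t["P"].to_numpy()))
    claimed = np.zeros(len(t), dtype=bool)
    chrom = t["CHR"].astype(str).to_numpy()
    pos = t["POS"].to_numpy()
    p = t["P"].to_numpy()
    ids = t["ID"].to_numpy()

    rows, members = [], []
    for i in order:
        if claimed[i] or p[i] > index_p:
            continue
        in_window = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & (p <= max(member_p, index_p))
        )
        in_window[i] = True
        claimed |= in_window
        member_idx = np.flatnonzero(in_window)
        rows.append(
            {
                "index_id": ids[i],
                "chrom": chrom[i],
                "pos": int(pos[i]),
                "start": int(pos[member_idx].min()),
                "end": int(pos[member_idx].max()),
                "min_p": float(p[i]),
                "n_members": int(len(member_idx)),
                "trait": stats.trait,
            }
        )
        members.append(list(ids[member_idx]))
    if not rows:
        return LocusTable.empty(stats.trait)
    return LocusTable(pd.DataFrame(rows), members)


def aggregate_traits(stats_list: list[SummaryStats], tag: str = "min_p") -> SummaryStats:
    """Per-variant minimum p across traits, carrying the winning trait's row."""
    if not stats_list:
        raise ValueError("need at least one summary-statistics table")
    ids = stats_list[0].table["ID"].to_numpy()
    for ss in stats_list[1:]:
        if not np.array_equal(ss.table["ID"].to_numpy(), ids):
            raise ValueError("summary statistics must share one variant universe")
    P = np.column_stack([ss.table["P"].to_numpy() for ss in stats_list])
    winner = P.argmin(axis=1)
    frames = [ss.table for ss in stats_list]
    rows = [frames[w].iloc[j] for j, w in enumerate(winner)]
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["SOURCE_TRAIT"] = [stats_list[w].trait for w in winner]
    return SummaryStats(table, trait=tag)


def merge_loci(
    a: LocusTable, b: LocusTable, window_bp: int = 250_000
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match loci whose index variants lie within ``window_bp`` on one chrom.

    Greedy nearest-distance matching; returns (shared pairs of row indices
    in a and b, unmatched a rows, unmatched b rows).
    """
    pairs = []
    for i, ra in a.table.iterrows():
        for j, rb in b.table.iterrows():
            if str(ra["chrom"]) == str(rb["chrom"]) and abs(int(ra["pos"]) - int(rb["pos"])) <= window_bp:
                pairs.append((abs(int(ra["pos"]) - int(rb["pos"])), i, j))
    pairs.sort()
    used_a, used_b, shared = set(), set(), []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        shared.append((i, j))
        used_a.add(i)
        used_b.add(j)
    a_only = [i for i in range(len(a)) if i not in used_a]
    b_only = [j for j in range(len(b)) if j not in used_b]
    return shared, a_only, b_only


def replicate_split(
    panel: GenotypePanel,
    traits: np.ndarray | pd.DataFrame,
    covariates: CovariateTable | None,
    frac: float = 0.65,
    index_p: float = 1e-9,
    replication_alpha: float = 0.05,
    window_bp: int = 250_000,
    member_p: float = 5e-8,
    seed: int = 0,
    trait_names: list[str] | None = None,
) -> tuple[LocusTable, LocusTable]:
    """Discovery/replication design on disjoint random sample splits.

    A discovery locus replicates when its index variant reaches
    ``replication_alpha`` in the replication scan with a concordant beta
    sign. Returns (replicated loci, all discovery loci) pooled over traits.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    if isinstance(traits, pd.DataFrame):
        trait_names = trait_names or [str(c) for c in traits.columns]
        traits = traits.to_numpy(float)
    traits = np.atleast_2d(np.asarray(traits, float))
    if traits.shape[0] != panel.n_samples:
        traits = traits.T
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_samples)
    n_disc = int(round(frac * panel.n_samples))
    if n_disc < 2 or panel.n_samples - n_disc < 2:
        raise ValueError("split leaves fewer than 2 samples in a cohort")
    disc_idx, repl_idx = perm[:n_disc], perm[n_disc:]

    def scan_subset(idx):
        sub = panel.subset(sample_idx=idx)
        cov = covariates.align(sub.sample_ids) if covariates is not None else None
        return association_scan(sub, traits[idx], cov, trait_names=trait_names)

    disc_stats = scan_subset(disc_idx)
    repl_stats = scan_subset(repl_idx)

    disc_rows, disc_members, repl_rows, repl_members = [], [], [], []
    for d_ss, r_ss in zip(disc_stats, repl_stats):
        loci = clump(d_ss, window_bp=window_bp, index_p=index_p, member_p=member_p)
        r_tab = r_ss.table.set_index("ID")
        d_tab = d_ss.table.set_index("ID")
        for row, mem in zip(loci.table.itertuples(index=False), loci.members):
            disc_rows.append(row._asdict())
            disc_members.append(mem)
            idx_id = row.index_id
            if idx_id not in r_tab.index:
                continue
            p_rep = float(r_tab.loc[idx_id, "P"])
            sign_ok = np.sign(r_tab.loc[idx_id, "BETA"]) == np.sign(d_tab.loc[idx_id, "BETA"])
            if p_rep < replication_alpha and sign_ok:
                repl_rows.append(row._asdict())
                repl_members.append(mem)

    def build(rows, members):
        if not rows:
            return LocusTable.empty("replication")
        return LocusTable(pd.DataFrame(rows), members)

    return build(repl_rows, repl_members), build(disc_rows, disc_members)
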