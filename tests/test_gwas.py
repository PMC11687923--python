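"""Association-scan correctness against explicit regression oracles,
QC filter enumeration, clumping greedy semantics, threshold arithmetic,
aggregation, locus matching, and the replication design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import latentgwas as lg
from latentgwas.types import MISSING

from conftest import make_sumstats


class TestHweTest:
    def test_exact_proportions_give_p_one(self):
        assert lg.hwe_test(25, 50, 25) == 1.0

    def test_complete_het_deficit(self):
        assert lg.hwe_test(100, 0, 100) < 1e-10

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_chi_square_formula(self, counts):
        n_AA, n_Aa, n_aa = counts
        n = n_AA + n_Aa + n_aa
        p = (2 * n_AA + n_Aa) / (2 * n)
        exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        if (exp == 0).any():
            expected = 1.0
        else:
            chi2 = (([n_AA, n_Aa, n_aa] - exp) ** 2 / exp).sum()
            expected = max(sps.chi2.sf(chi2, 1), 5e-324)
        assert lg.hwe_test(n_AA, n_Aa, n_aa) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            lg.hwe_test(0, 0, 0)


def _panel_from_dosages(dosages, pos=None, chrom=None):
    n, m = dosages.shape
    pos = pos if pos is not None else (np.arange(m) * 1000 + 1)
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    return lg.GenotypePanel([f"S{i}" for i in range(n)], variants, dosages)


class TestQcFilter:
    def test_monomorphic_removed_by_maf(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(100, 5)).astype(float)
        d[:, 2] = 0.0  # monomorphic
        panel = _panel_from_dosages(d)
        kept, report = lg.qc_filter(panel)
        assert "v2" not in kept.variants["id"].tolist()
        assert dict(report.steps)["maf"] >= 1

    def test_duplicate_variant_pruned(self):
        rng = np.random.default_rng(1)
        base = (rng.binomial(1, 0.4, (200, 1)) + rng.binomial(1, 0.4, (200, 1))).astype(float)
        other = (rng.binomial(1, 0.4, (200, 1)) + rng.binomial(1, 0.4, (200, 1))).astype(float)
        d = np.hstack([base, base, other])
        panel = _panel_from_dosages(d, pos=[1000, 2000, 3000])
        kept, report = lg.qc_filter(panel)
        assert dict(report.steps)["ld_prune"] == 1
        assert kept.variants["id"].tolist()[0] == "v0"  # earlier position kept

    def test_constructed_panel_matches_enumeration(self):
        """20 variants with hand-planted casualties for each filter."""
        rng = np.random.default_rng(2)
        n = 400
        cols, expect_removed = [], {"maf": 0, "missingness": 0, "hwe": 0, "ld_prune": 0}
        # 14 clean HWE variants
        for j in range(14):
            p = 0.3
            cols.append(rng.binomial(1, p, n) + rng.binomial(1, p, n))
        # 2 monomorphic (MAF 0 < 0.001)
        for j in range(2):
            cols.append(np.zeros(n))
            expect_removed["maf"] += 1
        # 1 high-missingness variant (20% missing)
        c = rng.binomial(1, 0.3, n) + rng.binomial(1, 0.3, n).astype(float)
        c[: n // 5] = MISSING
        cols.append(c)
        expect_removed["missingness"] += 1
        # 2 HWE violations: all hets
        cols.append(np.ones(n))  # all heterozygous
        het_deficit = np.repeat([0.0, 2.0], n // 2)  # no hets at freq 0.5
        cols.append(het_deficit)
        expect_removed["hwe"] += 2
        # 1 duplicate of the first clean variant, placed within the window
        cols.append(cols[0].copy())
        expect_removed["ld_prune"] += 1
        d = np.column_stack([c.astype(float) for c in cols])
        panel = _panel_from_dosages(d)
        kept, report = lg.qc_filter(panel)
        assert dict(report.steps) == expect_removed
        assert report.survivors == 20 - sum(expect_removed.values())

    def test_counts_add_up(self, small_panel):
        _, report = lg.qc_filter(small_panel)
        assert sum(dict(report.steps).values()) + report.survivors == small_panel.n_variants


class TestAssociationScan:
    def test_perfect_linear_trait(self):
        panel = _panel_from_dosages(
            np.random.default_rng(3).integers(0, 3, size=(50, 3)).astype(float)
        )
        y = 2.0 * panel.dosages[:, 1]
        ss = lg.association_scan(panel, y)[0]
        assert ss.table.loc[1, "BETA"] == pytest.approx(2.0, abs=1e-8)
        assert ss.table.loc[1, "P"] < 1e-30

    def test_matches_statsmodels_oracle(self, small_panel):
        """Betas and p-values equal per-variant explicit OLS within 1e-8."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = small_panel.n_samples
        cov = lg.CovariateTable(
            pd.DataFrame(
                {
                    "age": rng.normal(60, 8, n),
                    "sex": rng.integers(0, 2, n).astype(float),
                    "batch": rng.integers(0, 3, n),
                },
                index=pd.Index(small_panel.sample_ids, name="sample_id"),
            )
        )
        y = rng.standard_normal(n) + 0.1 * cov.table["age"].to_numpy()
        ss = lg.association_scan(small_panel, y, cov)[0]
        C = cov.design_matrix()
        for j in rng.choice(small_panel.n_variants, 50, replace=False):
            X = np.column_stack([C, small_panel.dosages[:, j]])
            fit = sm.OLS(y, X).fit()
            assert ss.table.loc[j, "BETA"] == pytest.approx(fit.params[-1], abs=1e-8)
            assert ss.table.loc[j, "P"] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_zero_variance_variant_flagged(self):
        d = np.random.default_rng(5).integers(0, 3, size=(60, 2)).astype(float)
        d[:, 0] = 1.0
        panel = _panel_from_dosages(d)
        ss = lg.association_scan(panel, np.random.default_rng(6).standard_normal(60))[0]
        row = ss.table.iloc[0]
        assert row["BETA"] == 0.0 and row["P"] == 1.0 and row["ZERO_VAR"] == 1

    def test_confounder_adjustment_removes_spurious_hit(self):
        """A trait driven by a confounder correlated with dosage loses its
        association once the confounder enters the design."""
        rng = np.random.default_rng(7)
        n = 800
        conf = rng.standard_normal(n)
        dose = np.clip(np.round(conf + rng.standard_normal(n) + 1.0), 0, 2)
        y = conf + 0.05 * rng.standard_normal(n)
        panel = _panel_from_dosages(dose[:, None])
        p_naive = lg.association_scan(panel, y)[0].table.loc[0, "P"]
        cov = lg.CovariateTable(
            pd.DataFrame(
                {"age": conf, "sex": np.zeros(n)},
                index=pd.Index(panel.sample_ids, name="sample_id"),
            )
        )
        p_adj = lg.association_scan(panel, y, cov)[0].table.loc[0, "P"]
        assert p_naive < 1e-10 and p_adj > 0.01

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(100, 1)).astype(float)
        d[:10, 0] = MISSING
        panel = _panel_from_dosages(d)
        y = rng.standard_normal(100)
        ss = lg.association_scan(panel, y)[0]
        assert np.isfinite(ss.table.loc[0, "P"])


class TestBonferroni:
    def test_twenty_pcs_genomewide(self):
        assert lg.bonferroni_threshold(5e-8, 20) == pytest.approx(2.5e-9, rel=1e-12)

    def test_traits_by_pcs_grid(self):
        thr = lg.bonferroni_threshold(0.05, 102 * 20)
        assert thr == pytest.approx(2.45e-5, rel=1e-3)
        assert f"{thr:.1e}" == "2.5e-05"

    def test_identity_and_errors(self):
        assert lg.bonferroni_threshold(0.013, 1) == 0.013
        with pytest.raises(ValueError):
            lg.bonferroni_threshold(0.05, 0)


class TestClump:
    def test_hand_run_greedy_example(self):
        ss = make_sumstats([100_000, 200_000, 600_000], [1e-12, 1e-10, 1e-11])
        loci = lg.clump(ss, window_bp=250_000, index_p=1e-9, member_p=1e-9)
        assert len(loci) == 2
        assert loci.table["index_id"].tolist() == ["v0", "v2"]
        assert sorted(loci.members[0]) == ["v0", "v1"]
        assert loci.members[1] == ["v2"]

    def test_no_eligible_index_empty(self):
        ss = make_sumstats([1000, 2000], [1e-6, 1e-5])
        assert len(lg.clump(ss, index_p=1e-9)) == 0

    def test_singleton_locus(self):
        ss = make_sumstats([1000], [1e-12])
        loci = lg.clump(ss)
        assert len(loci) == 1 and loci.members[0] == ["v0"]

    def test_members_partition_and_monotonicity(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(10_000_000, 200, replace=False))
        p = 10.0 ** rng.uniform(-15, 0, 200)
        ss = make_sumstats(pos, p)
        loci = lg.clump(ss, index_p=1e-9, member_p=5e-8)
        all_members = [m for mem in loci.members for m in mem]
        assert len(all_members) == len(set(all_members))  # at most one locus each
        counts = [
            len(lg.clump(ss, index_p=ip, member_p=5e-8)) for ip in (1e-12, 1e-9, 1e-6)
        ]
        assert counts == sorted(counts)

    def test_index_has_min_p_of_members(self):
        rng = np.random.default_rng(10)
        pos = np.sort(rng.choice(5_000_000, 100, replace=False))
        ss = make_sumstats(pos, 10.0 ** rng.uniform(-14, -2, 100))
        loci = lg.clump(ss)
        t = ss.table.set_index("ID")
        for row, members in zip(loci.table.itertuples(), loci.members):
            assert row.min_p == min(t.loc[m, "P"] for m in members)
            assert t.loc[row.index_id, "P"] == row.min_p


class TestAggregateAndMerge:
    def test_single_trait_identity(self):
        ss = make_sumstats([1000, 2000], [1e-4, 1e-5])
        agg = lg.aggregate_traits([ss])
        assert np.array_equal(agg.table["P"].to_numpy(), ss.table["P"].to_numpy())

    def test_elementwise_min_with_loop_oracle(self):
        rng = np.random.default_rng(11)
        a = make_sumstats(np.arange(1, 51) * 1000, 10.0 ** rng.uniform(-9, 0, 50))
        b = make_sumstats(np.arange(1, 51) * 1000, 10.0 ** rng.uniform(-9, 0, 50))
        agg = lg.aggregate_traits([a, b])
        for j in range(50):
            expected = min(a.table.loc[j, "P"], b.table.loc[j, "P"])
            assert agg.table.loc[j, "P"] == expected
        assert (agg.table["P"].to_numpy() <= a.table["P"].to_numpy()).all()

    def test_merge_identical_all_shared(self):
        ss = make_sumstats([100_000, 900_000], [1e-12, 1e-13])
        loci = lg.clump(ss)
        shared, a_only, b_only = lg.merge_loci(loci, loci)
        assert len(shared) == 2 and not a_only and not b_only

    def test_merge_disjoint_chromosomes(self):
        a = lg.clump(make_sumstats([100_000], [1e-12], chrom="1"))
        b = lg.clump(make_sumstats([100_000], [1e-12], chrom="2"))
        shared, a_only, b_only = lg.merge_loci(a, b)
        assert not shared and a_only == [0] and b_only == [0]

    def test_merge_constructed_overlap(self):
        a = lg.clump(make_sumstats([100_000, 900_000], [1e-12, 1e-12]))
        b = lg.clump(make_sumstats([180_000, 2_000_000], [1e-12, 1e-12]))
        shared, a_only, b_only = lg.merge_loci(a, b, window_bp=250_000)
        assert shared == [(0, 0)] and a_only == [1] and b_only == [1]


class TestReplicateSplit:
    def test_planted_effect_replicates(self):
        hits = 0
        for seed in range(5):
            panel = lg.simulate_genotypes(1200, 50, maf_range=(0.3, 0.5),
                                          block_corr=0.0, seed=seed)
            rng = np.random.default_rng(100 + seed)
            y = 0.6 * panel.dosages[:, 10] + rng.standard_normal(1200)
            repl, disc = lg.replicate_split(panel, y, None, frac=0.65, seed=seed)
            hits += len(repl) >= 1
        assert hits >= 4

    def test_null_panel_no_replicated_loci(self):
        panel = lg.simulate_genotypes(400, 50, seed=31)
        y = np.random.default_rng(32).standard_normal(400)
        repl, _ = lg.replicate_split(panel, y, None, frac=0.5, seed=33)
        assert len(repl) == 0

    def test_degenerate_fraction_rejected(self, small_panel):
        y = np.zeros(small_panel.n_samples)
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                lg.replicate_split(small_panel, y, None, frac=frac)
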