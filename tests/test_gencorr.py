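"""LD scores against brute-force enumeration, LD-score-regression parameter
recovery, self-pair genetic correlation, and the shared-region screen."""

import numpy as np
import pandas as pd
import pytest

import latentgwas as lg

from conftest import make_sumstats


def _ld_table(ld, pos=None):
    M = len(ld)
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(M)],
            "chrom": "1",
            "pos": pos if pos is not None else np.arange(M) * 1000 + 1,
            "ld_score": np.asarray(ld, float),
        }
    )


def _spread_ld(M, seed=0):
    return np.random.default_rng(seed).uniform(1, 20, M)


class TestLdScores:
    def test_isolated_variant_self_term_only(self):
        rng = np.random.default_rng(0)
        d = (rng.binomial(1, 0.3, (500, 2)) + rng.binomial(1, 0.3, (500, 2))).astype(float)
        variants = pd.DataFrame(
            {"id": ["a", "b"], "chrom": "1", "pos": [1, 5_000_000],
             "ref": "A", "alt": "G"}
        )
        panel = lg.GenotypePanel([f"S{i}" for i in range(500)], variants, d)
        ld = lg.ld_scores(panel, window_bp=1_000_000)
        assert ld["ld_score"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_duplicated_pair_scores_near_two(self):
        rng = np.random.default_rng(1)
        base = (rng.binomial(1, 0.4, 1000) + rng.binomial(1, 0.4, 1000)).astype(float)
        d = np.column_stack([base, base])
        variants = pd.DataFrame(
            {"id": ["a", "b"], "chrom": "1", "pos": [1000, 2000], "ref": "A", "alt": "G"}
        )
        panel = lg.GenotypePanel([f"S{i}" for i in range(1000)], variants, d)
        ld = lg.ld_scores(panel)
        assert np.allclose(ld["ld_score"], 2.0, atol=0.05)

    def test_matches_brute_force_double_loop(self, small_panel):
        sub = small_panel.subset(variant_idx=np.arange(50))
        ld = lg.ld_scores(sub, window_bp=1_000_000)
        G = sub.dosages
        n = G.shape[0]
        Gs = (G - G.mean(0)) / G.std(0)
        pos = sub.variants["pos"].to_numpy()
        for j in range(50):
            total = 0.0
            for k in range(50):
                if abs(pos[k] - pos[j]) <= 1_000_000:
                    r2 = (float(Gs[:, j] @ Gs[:, k]) / n) ** 2
                    total += r2 - (1 - r2) / (n - 2)
            assert ld["ld_score"].iloc[j] == pytest.approx(total, abs=1e-8)

    def test_monomorphic_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        d = (rng.binomial(1, 0.3, (100, 3)) + rng.binomial(1, 0.3, (100, 3))).astype(float)
        d[:, 1] = 0.0
        variants = pd.DataFrame(
            {"id": ["a", "b", "c"], "chrom": "1", "pos": [1, 2, 3], "ref": "A", "alt": "G"}
        )
        panel = lg.GenotypePanel([f"S{i}" for i in range(100)], variants, d)
        with pytest.warns(UserWarning):
            ld = lg.ld_scores(panel)
        assert list(ld["id"]) == ["a", "c"]


class TestLdscH2:
    def test_too_few_variants_refused(self):
        ld = _ld_table(np.ones(20))
        s1, _ = lg.simulate_sumstats(np.ones(20), 1000, 1000, 0.1, 0.1, 0.0, seed=1)
        with pytest.raises(ValueError):
            lg.ldsc_h2(s1, ld)

    def test_row_order_invariance(self):
        M = 2000
        ld_vals = _spread_ld(M, 3)
        ld = _ld_table(ld_vals)
        s1, _ = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.2, 0.2, 0.0, seed=4)
        fit = lg.ldsc_h2(s1, ld)
        perm = np.random.default_rng(5).permutation(M)
        s_perm = lg.SummaryStats(s1.table.iloc[perm].reset_index(drop=True), trait=s1.trait)
        fit_perm = lg.ldsc_h2(s_perm, ld)
        assert fit.h2 == pytest.approx(fit_perm.h2, abs=1e-10)

    def test_null_h2_within_two_se(self):
        M = 3000
        ld_vals = _spread_ld(M, 6)
        ld = _ld_table(ld_vals)
        covered = 0
        for seed in range(20):
            s1, _ = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.0, 0.0, 0.0, seed=seed)
            fit = lg.ldsc_h2(s1, ld)
            covered += abs(fit.h2) <= 2 * fit.h2_se
        assert covered >= 18

    def test_h2_recovery_and_unit_intercept(self):
        M = 3000
        ld_vals = _spread_ld(M, 7)
        ld = _ld_table(ld_vals)
        h2s, intercept_ok = [], 0
        for seed in range(15):
            s1, _ = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.2, 0.2, 0.0, seed=seed)
            fit = lg.ldsc_h2(s1, ld)
            h2s.append(fit.h2)
            intercept_ok += abs(fit.intercept - 1.0) < 2 * fit.intercept_se
        assert 0.15 < np.mean(h2s) < 0.25
        assert intercept_ok >= 12

    def test_bias_shrinks_with_scale(self):
        """Mean absolute error of h2 decreases as M (and info) grows."""
        errs = []
        for M in (500, 2000, 8000):
            ld_vals = _spread_ld(M, 8)
            ld = _ld_table(ld_vals)
            e = []
            for seed in range(10):
                s1, _ = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.2, 0.2, 0.0,
                                             seed=1000 + seed)
                e.append(abs(lg.ldsc_h2(s1, ld).h2 - 0.2))
            errs.append(np.mean(e))
        assert errs[0] > errs[-1]


class TestLdscRg:
    def test_self_pair_rg_near_one(self):
        M = 3000
        ld_vals = _spread_ld(M, 9)
        ld = _ld_table(ld_vals)
        s1, _ = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.3, 0.3, 0.0, seed=10)
        fit = lg.ldsc_rg(s1, s1, ld)
        assert fit.rg == pytest.approx(1.0, abs=0.05)

    def test_negative_rg_sign_recovered(self):
        M = 3000
        ld_vals = _spread_ld(M, 11)
        ld = _ld_table(ld_vals)
        correct = 0
        for seed in range(20):
            s1, s2 = lg.simulate_sumstats(ld_vals, 20000, 20000, 0.3, 0.3, -0.5, seed=seed)
            fit = lg.ldsc_rg(s1, s2, ld)
            correct += fit.rg is not None and fit.rg < 0
        assert correct >= 19

    def test_rg_clipped_and_raw_logged(self):
        M = 1000
        ld_vals = _spread_ld(M, 12)
        ld = _ld_table(ld_vals)
        # tiny h2 with strong covariance pushes the ratio far above 1
        s1, s2 = lg.simulate_sumstats(ld_vals, 5000, 5000, 0.02, 0.02, 1.0, seed=13)
        fit = lg.ldsc_rg(s1, s2, ld)
        if fit.rg is not None:
            assert -1.25 <= fit.rg <= 1.25
            assert fit.rg_raw is not None


class TestSharedRegions:
    def _stats(self, pos, z, p, trait):
        ss = make_sumstats(pos, p)
        ss.table["Z"] = z
        ss.trait = trait
        return lg.SummaryStats(ss.table, trait=trait)

    def test_nothing_passes_p_filter(self):
        pos = [1000, 2000]
        focal = self._stats(pos, [5.0, 5.0], [1e-2, 1e-2], "focal")
        b = self._stats(pos, [5.0, 5.0], [1e-6, 1e-6], "b")
        c = self._stats(pos, [5.0, 5.0], [1e-6, 1e-6], "c")
        assert lg.shared_regions(focal, b, c, rg_signs=(None, None)) == []

    def test_two_planted_clusters(self):
        pos = [100_000, 150_000, 700_000, 760_000, 5_000_000]
        zf = [6.0, 5.0, -6.5, -5.0, 0.1]
        p = [1e-8, 1e-6, 1e-9, 1e-6, 0.9]
        focal = self._stats(pos, zf, p, "focal")
        b = self._stats(pos, [4.0, 4.0, -4.0, -4.0, 0.0], [1e-4] * 5, "b")
        c = self._stats(pos, [3.5, 3.5, -3.5, -3.5, 0.0], [1e-3] * 5, "c")
        regions = lg.shared_regions(focal, b, c, p_max=1e-4, zprod_min=15.0,
                                    window_bp=250_000, rg_signs=(None, 1))
        assert len(regions) == 2
        centrals = {r["central_id"] for r in regions}
        assert centrals == {"v2", "v0"}  # largest |z_focal*z_b| per cluster
        for r in regions:
            assert len(r["members"]) == 2

    def test_sign_flip_excludes_candidates(self):
        pos = [100_000]
        focal = self._stats(pos, [6.0], [1e-8], "focal")
        b = self._stats(pos, [4.0], [1e-4], "b")
        c = self._stats(pos, [3.0], [1e-3], "c")
        assert len(lg.shared_regions(focal, b, c, rg_signs=(None, 1))) == 1
        assert len(lg.shared_regions(focal, b, c, rg_signs=(None, -1))) == 0

    def test_regions_partition_candidates(self):
        rng = np.random.default_rng(14)
        m = 50
        pos = np.sort(rng.choice(20_000_000, m, replace=False))
        z = rng.uniform(4, 8, m) * rng.choice([-1, 1], m)
        p = 10.0 ** rng.uniform(-9, -5, m)
        focal = self._stats(pos, z, p, "focal")
        b = self._stats(pos, rng.uniform(3, 6, m), [1e-4] * m, "b")
        c = self._stats(pos, rng.uniform(3, 6, m), [1e-4] * m, "c")
        regions = lg.shared_regions(focal, b, c, rg_signs=(None, None))
        members = [mm for r in regions for mm in r["members"]]
        assert len(members) == len(set(members))
        # non-overlap of region windows around centrals by construction:
        # every member lies within the window of exactly one central
        for r in regions:
            for mm in r["members"]:
                i = list(focal.table["ID"]).index(mm)
                assert abs(int(focal.table.loc[i, "POS"]) - r["pos"]) <= 250_000

    def test_empty_overlap_rejected(self):
        a = self._stats([1000], [5.0], [1e-8], "a")
        btab = self._stats([1000], [5.0], [1e-8], "b")
        btab.table["ID"] = ["other"]
        b = lg.SummaryStats(btab.table, trait="b")
        with pytest.raises(ValueError):
            lg.shared_regions(a, b, b)
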