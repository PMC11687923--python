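"""LD-score regression: heritability, genetic correlation, shared regions.

Summary statistics are simulated from the exact expectation model LDSC
assumes (E[chi^2] = 1 + N h^2 l/M), so the regression should recover the
generating h^2 = 0.2 and rg = 0.5 up to sampling noise.
"""

import numpy as np

import latentgwas as lg

M, N = 5000, 20_000
ld_vals = np.random.default_rng(0).uniform(1, 20, M)

s1, s2 = lg.simulate_sumstats(ld_vals, N, N, h2_1=0.2, h2_2=0.2, rg=0.5,
                              n_variants=M, seed=1)
import pandas as pd
ld = pd.DataFrame({"id": s1.table["ID"], "chrom": s1.table["CHR"],
                   "pos": s1.table["POS"], "ld_score": ld_vals})

fit = lg.ldsc_h2(s1, ld)
print(f"h2 = {fit.h2:.3f} +/- {fit.h2_se:.3f} (truth 0.2), "
      f"intercept {fit.intercept:.3f} (1.0 means no confounding)")

rg = lg.ldsc_rg(s1, s2, ld)
print(f"rg = {rg.rg:.3f} +/- {rg.rg_se:.3f} (truth 0.5)")

regions = lg.shared_regions(s1, s2, s2, p_max=1e-4, zprod_min=15,
                            rg_signs=(None, None))
print(f"{len(regions)} region(s) where strong focal variants also carry "
      "large z-score products with both secondary traits")
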