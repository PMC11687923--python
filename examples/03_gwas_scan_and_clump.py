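"""QC a panel, scan a trait with covariate adjustment, clump into loci.

The trait plants one causal variant at 4% explained variance so that the
scan's smallest p-value lands on (or next to) the truth, and clumping at
the family-wise threshold groups its LD block into a single locus.
"""

import numpy as np

import latentgwas as lg

panel = lg.simulate_genotypes(2000, 1000, maf_range=(0.1, 0.5),
                              ld_block_size=10, block_corr=0.6,
                              missing_rate=0.01, seed=3)
qc_panel, report = lg.qc_filter(panel)
print("QC:", report.as_dict())

rng = np.random.default_rng(4)
causal = 250  # a block-start variant
g = qc_panel.dosages_imputed()[:, causal]
gz = (g - g.mean()) / g.std()
y = np.sqrt(0.04) * gz + np.sqrt(0.96) * rng.standard_normal(qc_panel.n_samples)

stats = lg.association_scan(qc_panel, y)[0]
top = stats.table.nsmallest(1, "P").iloc[0]
print(f"top hit: {top['ID']} at {top['CHR']}:{top['POS']} p={top['P']:.2e} "
      f"(planted: {qc_panel.variants.loc[causal, 'id']})")

threshold = lg.bonferroni_threshold(5e-8, 20)
print(f"family-wise index threshold for 20 traits: {threshold:.1e}")

loci = lg.clump(stats, window_bp=250_000, index_p=1e-9, member_p=5e-8)
print(f"{len(loci)} independent locus/loci; members of the first: "
      f"{loci.members[0] if len(loci) else '-'} "
      "(the causal variant's LD block collapses to one locus)")
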