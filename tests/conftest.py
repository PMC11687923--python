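import numpy as np
import pandas as pd
import pytest

import latentgwas as lg


@pytest.fixture(scope="session")
def small_panel() -> lg.GenotypePanel:
    """1000 samples x 300 variants with LD blocks, no missingness."""
    return lg.simulate_genotypes(
        1000, 300, maf_range=(0.1, 0.4), ld_block_size=10, block_corr=0.6, seed=11
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """200-sample cohort with a planted radius effect and covariate effects."""
    panel = lg.simulate_genotypes(200, 60, maf_range=(0.2, 0.4), seed=5)
    effects = lg.EffectSpec(
        entries=[(0, 1, 0.4, "radius")], age_slope=0.4, sex_offset=0.2, noise_sd=0.1
    )
    volumes, covariates, dementia = lg.simulate_cohort(
        panel, effects, volume_shape=(16, 16, 16), n_rois=4, seed=6
    )
    return panel, effects, volumes, covariates, dementia


def make_sumstats(pos, p, chrom="1", beta=None, z=None, n=1000):
    """Hand-built SummaryStats for clumping/aggregation tests."""
    m = len(pos)
    p = np.asarray(p, float)
    if z is None:
        from scipy import stats as sps

        z = sps.norm.isf(p / 2)
    if beta is None:
        beta = z / np.sqrt(n)
    se = np.abs(np.asarray(beta)) / np.maximum(np.abs(z), 1e-12)
    se = np.where(se <= 0, 1e-3, se)
    table = pd.DataFrame(
        {
            "CHR": chrom if np.isscalar(chrom) else list(chrom),
            "POS": list(pos),
            "ID": [f"v{i}" for i in range(m)],
            "A1": "G",
            "A2": "A",
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": p,
            "N": n,
            "MAF": 0.3,
        }
    )
    return lg.SummaryStats(table, trait="toy")
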