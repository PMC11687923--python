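"""Plotting helpers: Manhattan plot of summary statistics and a mid-slice
view of a statistical parametric map. Kept deliberately small — figures are
a convenience, not a pipeline stage.
"""

from __future__ import annotations

import numpy as np

from .interpret import SPMap
from .types import SummaryStats


def manhattan(stats: SummaryStats, ax=None, threshold: float = 2.5e-9,
              suggestive: float = 5e-8, p_floor: float = 1e-40):
    """Manhattan plot with the suggestive and family-wise thresholds drawn.

    p-values below ``p_floor`` are truncated for display.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = stats.table.sort_values(["CHR", "POS"])
    logp = -np.log10(np.maximum(t["P"].to_numpy(float), p_floor))
    x = np.arange(len(t))
    for i, (_, grp) in enumerate(t.groupby("CHR", sort=False)):
        sel = t["CHR"].to_numpy() == grp["CHR"].iloc[0]
        ax.scatter(x[sel], logp[sel], s=4, color=f"C{i % 2}")
    ax.axhline(-np.log10(suggestive), ls="--", color="grey", lw=0.8)
    ax.axhline(-np.log10(threshold), ls="-", color="black", lw=0.8)
    ax.set_xlabel("variant rank (by position)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(stats.trait)
    return ax


def spm_slice(spm: SPMap, axis: int = 2, index: int | None = None, ax=None):
    """Mid-volume slice of the t-map, masking sub-threshold voxels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.moveaxis(spm.t, axis, 0)
    sig = np.moveaxis(spm.significant, axis, 0)
    idx = t.shape[0] // 2 if index is None else index
    shown = np.where(sig[idx], t[idx], np.nan)
    im = ax.imshow(shown.T, cmap="coolwarm", origin="lower")
    ax.set_title(f"|t| >= {spm.threshold:.2f}")
    plt.colorbar(im, ax=ax, label="t")
    return ax
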