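"""Small plotting helpers (matplotlib) for the two headline comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd


def h2_boxplots(real: pd.DataFrame, permuted: pd.DataFrame, ax=None):
    """Side-by-side box plots of real vs permuted module heritabilities.

    ``real`` and ``permuted`` carry columns ``tcoe_id`` and ``h2``; one
    box pair per temporal co-expression set.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    sets = list(pd.unique(real["tcoe_id"]))
    pos = np.arange(len(sets), dtype=float)
    rdata = [real.loc[real["tcoe_id"] == s, "h2"].to_numpy() for s in sets]
    pdata = [permuted.loc[permuted["tcoe_id"] == s, "h2"].to_numpy()
             for s in sets]
    bp1 = ax.boxplot(rdata, positions=pos - 0.18, widths=0.3,
                     patch_artist=True)
    bp2 = ax.boxplot(pdata, positions=pos + 0.18, widths=0.3,
                     patch_artist=True)
    for box in bp1["boxes"]:
        box.set_facecolor("tab:red")
    for box in bp2["boxes"]:
        box.set_facecolor("tab:blue")
    ax.set_xticks(pos)
    ax.set_xticklabels(sets, rotation=90)
    ax.set_ylabel("heritability of module PC1")
    ax.set_ylim(-0.02, 1.02)
    return ax


def pvalue_comparison(observed_p, permuted_p, ax=None, bins: int = 20):
    """Overlaid histograms of observed vs permutation regression p-values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    edges = np.linspace(0, 1, bins + 1)
    ax.hist(np.asarray(observed_p), bins=edges, density=True, alpha=0.6,
            label="observed", color="tab:red")
    ax.hist(np.asarray(permuted_p), bins=edges, density=True, alpha=0.6,
            label="permuted", color="tab:blue")
    ax.set_xlabel("regression p-value")
    ax.set_ylabel("density")
    ax.legend()
    return ax
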