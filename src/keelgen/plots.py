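"""Optional Manhattan and QQ plots for GWAS results."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan", "qq"]


def manhattan(results: pd.DataFrame, ax=None, column: str = "neglog10_p_add_corr",
              threshold: float | None = None):
    """Manhattan plot of a -log10(p) column, chromosomes alternating shade."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    df = results.dropna(subset=[column]).copy()
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp[column], s=4, color="C0" if i % 2 else "C7", rasterized=True)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + 1
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax


def qq(results: pd.DataFrame, ax=None, column: str = "neglog10_p_add"):
    """QQ plot of observed vs expected -log10(p) with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    obs = np.sort(results[column].dropna().to_numpy())[::-1]
    m = obs.size
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    ax.scatter(exp, obs, s=5)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    return ax
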