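"""Simple diagnostic plots for screening and stability results."""

from __future__ import annotations

import numpy as np

from .data import CtMatrix
from .stability import StabilityResults, _as_frame


def ct_boxplot(ct, ax=None, order_by_median: bool = True):
    """Per-gene boxplot of absolute Ct values (flatter = more stable)."""
    import matplotlib.pyplot as plt

    vf = _as_frame(ct)
    if order_by_median:
        vf = vf.loc[vf.median(axis=1).sort_values().index]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.5 * len(vf)), 4))
    ax.boxplot([row for _, row in vf.iterrows()], tick_labels=list(vf.index))
    ax.set_ylabel("Ct (cycles)")
    ax.tick_params(axis="x", rotation=90)
    return ax


def stability_bars(results: StabilityResults, method: str | None = None, ax=None):
    """Bar chart of one method's stability values (or the final score),
    most stable gene first."""
    import matplotlib.pyplot as plt

    if method is None:
        vals = results.comprehensive["score"]
        label = "comprehensive score"
    else:
        vals = results.values[method]
        label = method
    vals = vals.sort_values()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.5 * len(vals)), 4))
    ax.bar(np.arange(len(vals)), vals.to_numpy())
    ax.set_xticks(np.arange(len(vals)), list(vals.index), rotation=90)
    ax.set_ylabel(label)
    return ax


def pairwise_variation_plot(results: StabilityResults, ax=None, cutoff: float = 0.15):
    """geNorm V_k bars with the conventional 0.15 guide line (below it,
    adding the (k+1)-th reference gene is unnecessary)."""
    import matplotlib.pyplot as plt

    if results.genorm is None:
        raise ValueError("results carry no geNorm output")
    v = results.genorm.pairwise_variation
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.6 * len(v)), 3.5))
    ax.bar(np.arange(len(v)), v.to_numpy())
    ax.axhline(cutoff, color="0.4", ls="--", lw=1)
    ax.set_xticks(np.arange(len(v)), list(v.index))
    ax.set_ylabel("pairwise variation V")
    return ax
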