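"""Bland-Altman plotting."""

from __future__ import annotations

import numpy as np

from .repeatability import BAResult, PairedSeries


def bland_altman_plot(series: PairedSeries, result: BAResult, ax=None,
                      title: str | None = None):
    """Mean-vs-difference scatter with bias and limits-of-agreement lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = (np.asarray(series.values_a, float)
             + np.asarray(series.values_b, float)) / 2.0
    ax.scatter(means, series.differences, s=8, alpha=0.4, edgecolors="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.2f}")
    for y, lab in ((result.loa_upper, f"ULoA {result.loa_upper:.2f}"),
                   (result.loa_lower, f"LLoA {result.loa_lower:.2f}")):
        ax.axhline(y, color="crimson", ls="--", lw=1.0, label=lab)
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference (second - first)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, loc="upper right")
    return ax
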