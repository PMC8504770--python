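"""Repeat-landscape style plots of the age distribution."""

from __future__ import annotations

from .ages import AgeHistogram


def plot_age_histogram(hist: AgeHistogram, ax=None, stratified: bool = True,
                       peaks: list[float] | None = None):
    """Copy number against percentage of substitutions from the consensus.

    Mirrors the usual repeat-landscape axes: x = divergence (%), y = copy
    number, optionally stacked by superfamily stratum, with detected burst
    positions marked.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    x = hist.centers * 100.0
    width = hist.bin_width * 100.0
    if stratified and hist.strata:
        bottom = None
        for label, counts in hist.strata.items():
            ax.bar(x, counts, width=width * 0.95, bottom=bottom, label=label)
            bottom = counts if bottom is None else bottom + counts
        ax.legend(fontsize=7, ncol=2)
    else:
        ax.bar(x, hist.counts, width=width * 0.95, color="#4472a8")
    if peaks:
        for p in peaks:
            ax.axvline(p * 100.0, color="crimson", linestyle="--", linewidth=1)
    ax.set_xlabel("substitutions from consensus (%)")
    ax.set_ylabel("copy number")
    return ax
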