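"""Allele-frequency track plots, one panel per chromosome."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .inference import TransmissionResults
from .windows import WindowProfile


def plot_af_profile(profile: WindowProfile, title: str = "",
                    crossovers=None, path=None):
    """B-allele-frequency track per chromosome; crossover midpoints, if
    given, are marked with black dots at the top of the panel."""
    chroms = list(dict.fromkeys(profile.df["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.2 * len(chroms)),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = profile.for_chrom(chrom)
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["mean_af"], ".", ms=2, color="tab:blue")
        ax.set_ylim(-0.05, 1.1)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
        ax.axhline(0.5, color="grey", lw=0.5, ls="--")
        if crossovers:
            for c in crossovers:
                if c.chrom == chrom:
                    ax.plot(c.midpoint / 1e6, 1.05, "ko", ms=3)
    axes[-1, 0].set_xlabel("position (Mb)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_results(results: TransmissionResults, path=None):
    c = results.classification
    return plot_af_profile(results.profile,
                           title=f"{c.sample_id} — {c.label}, {c.n_crossovers} CO",
                           crossovers=results.crossovers, path=path)
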