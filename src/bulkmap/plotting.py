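"""Optional per-chromosome SNP-index / delta plots with threshold bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_profile"]


def plot_profile(profile: pd.DataFrame, path: str) -> None:
    """Three-panel figure per chromosome column: high-bulk index, low-bulk
    index and windowed delta with the two-sided permutation threshold band."""
    chroms = list(pd.unique(profile["chrom"]))
    fig, axes = plt.subplots(
        3, max(len(chroms), 1), figsize=(5 * max(len(chroms), 1), 7),
        sharex="col", squeeze=False,
    )
    for j, chrom in enumerate(chroms):
        sub = profile[profile["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        axes[0][j].plot(mid, sub["mean_index_high"], lw=0.8, color="tab:blue")
        axes[0][j].set_title(chrom)
        axes[1][j].plot(mid, sub["mean_index_low"], lw=0.8, color="tab:orange")
        axes[2][j].plot(mid, sub["mean_delta"], lw=0.8, color="tab:green")
        if "threshold_lo" in sub:
            axes[2][j].fill_between(
                mid, sub["threshold_lo"], sub["threshold_hi"],
                color="tab:blue", alpha=0.2, lw=0,
            )
        axes[2][j].axhline(0, color="grey", lw=0.5)
        axes[2][j].set_xlabel("position (Mb)")
    axes[0][0].set_ylabel("index (high)")
    axes[1][0].set_ylabel("index (low)")
    axes[2][0].set_ylabel("delta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
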