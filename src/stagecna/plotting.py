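"""Convenience genome-wide frequency-track figure (gains up, losses down)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_frequency_tracks(
    gain_track: pd.DataFrame,
    loss_track: pd.DataFrame,
    title: str = "",
    path=None,
):
    """Mirror plot of per-marker gain (red, up) and loss (green, down)
    frequencies along the genome rank axis; chromosome boundaries dashed."""
    fig, ax = plt.subplots(figsize=(10, 3))
    x = range(len(gain_track))
    ax.fill_between(x, 0, gain_track["frequency"], color="crimson", step="mid",
                    label="gain")
    ax.fill_between(x, 0, -loss_track["frequency"], color="seagreen", step="mid",
                    label="loss")
    chroms = gain_track["chrom"].to_numpy()
    for i in range(1, len(chroms)):
        if chroms[i] != chroms[i - 1]:
            ax.axvline(i - 0.5, color="grey", ls="--", lw=0.5)
    ax.set_xlabel("genome probe rank")
    ax.set_ylabel("aberration frequency")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
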