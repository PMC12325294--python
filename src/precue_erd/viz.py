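"""Minimal scalp rendering of channel-wise statistics.

Draws each electrode as a colored disk at its approximate 10-20 position
with the fraction of significant participants annotated; intended for the
localization table, not for dense topographic interpolation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

# approximate 2-D projections of common 10-20 positions (x right, y front)
CHANNEL_POS = {
    "Fp1": (-0.3, 0.9), "Fp2": (0.3, 0.9),
    "F7": (-0.7, 0.5), "F3": (-0.4, 0.5), "Fz": (0.0, 0.5),
    "F4": (0.4, 0.5), "F8": (0.7, 0.5),
    "T7": (-0.9, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T8": (0.9, 0.0),
    "P7": (-0.7, -0.5), "P3": (-0.4, -0.5), "Pz": (0.0, -0.5),
    "P4": (0.4, -0.5), "P8": (0.7, -0.5),
    "O1": (-0.3, -0.9), "Oz": (0.0, -0.9), "O2": (0.3, -0.9),
}


def plot_channel_map(localization: pd.DataFrame, path: str, title: str = "") -> None:
    """Disk-per-electrode map of median r with % significant annotated."""
    fig, ax = plt.subplots(figsize=(5, 5))
    circle = plt.Circle((0, 0), 1.05, fill=False, color="k")
    ax.add_patch(circle)
    vals = localization.set_index("channel")
    vmax = max(abs(vals["median_r"]).max(), 1e-6)
    for ch, row in vals.iterrows():
        x, y = CHANNEL_POS.get(ch, (0.0, 0.0))
        sc = ax.scatter(
            x, y, s=900, c=[row["median_r"]], cmap="RdBu_r", vmin=-vmax, vmax=vmax,
            edgecolors="k",
        )
        ax.annotate(
            f"{ch}\n{row['fraction_significant']:.0%}",
            (x, y), ha="center", va="center", fontsize=7,
        )
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7, label="median Spearman r")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
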