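"""Minimal rendering of methylation profile panels (matplotlib).

Figure aesthetics are not a contract of this package; these helpers exist
so a run can be eyeballed quickly.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

CONTEXT_COLOURS = {"CGm": "tab:red", "CHGm": "tab:orange", "CHHm": "tab:blue"}


def plot_profile(tiles, path: str | Path, title: str = ""):
    """Per-tile CG/CHG/CHH methylation along one end."""
    fig, ax = plt.subplots(figsize=(9, 3))
    for col, colour in CONTEXT_COLOURS.items():
        if col in tiles.columns:
            ax.plot(tiles["start"], tiles[col], color=colour, label=col, lw=1)
    ax.set_xlabel("distance from terminus (bp)")
    ax.set_ylabel("methylation (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_boundary(tiles, path: str | Path, title: str = ""):
    """CHH methylation of the 35-bp boundary tiles, telomere shaded."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(tiles["end"], tiles["CHHm"], width=28, color="tab:blue")
    tel = tiles[tiles["zone"] == "Tel"]
    if len(tel):
        ax.axvspan(0, tel["end"].max(), color="grey", alpha=0.3)
    ax.set_xlabel("tile end position (bp)")
    ax.set_ylabel("CHHm (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
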