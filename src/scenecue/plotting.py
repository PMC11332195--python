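"""Optional matplotlib figures for ROC curves and encoding bin profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_roc", "plot_encoding_bins"]


def plot_roc(curves: dict, path=None, ax=None):
    """ROC curves keyed by label (e.g. duration), with AUC in the legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.fa, curve.hit, marker="o", ms=3, label=f"{label} (AUC={curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("False-alarm rate")
    ax.set_ylabel("Hit rate")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_encoding_bins(binned, comparison=None, path=None, ax=None):
    """Mean decoding r per depth bin for trained vs random model instances."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    for trained, color in ((True, "crimson"), (False, "black")):
        sub = binned[binned["trained"] == trained]
        agg = sub.groupby("bin")["mean_r"].mean()
        ax.plot(agg.index, agg.values, marker="o", color=color,
                label="trained" if trained else "random")
    if comparison is not None:
        sig = comparison[comparison["reject"]]
        ymax = binned["mean_r"].max()
        ax.scatter(sig["bin"], [ymax * 1.05] * len(sig), marker="*", color="crimson")
    ax.set_xlabel("Depth bin (1 = earliest, 10 = deepest)")
    ax.set_ylabel("Decoding r")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
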