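"""Figure builders: mutation-landscape heat map, signature bar panels, and the
cohort recurrence profile.  Uses matplotlib Figure objects directly so no GUI
backend is ever touched."""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from . import channels as ch

_SUB_COLORS = {
    "C>A": "#03BCEE", "C>G": "#010101", "C>T": "#E32926",
    "T>A": "#CAC9C9", "T>C": "#A1CE63", "T>G": "#EBC6C4",
}


def _save(fig: Figure, path) -> None:
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=120, bbox_inches="tight")


def mutation_landscape(calls: pd.DataFrame, path, top_genes: int = 25) -> None:
    """Gene x sample mutation heat map with per-gene totals."""
    muts = calls[calls["status"] == "accepted"] if "status" in calls.columns else calls
    muts = muts[muts["gene"] != ""]
    if not len(muts):
        fig = Figure(figsize=(4, 2))
        fig.suptitle("no accepted mutations")
        _save(fig, path)
        return
    counts = muts.groupby(["gene", "sample"]).size().unstack(fill_value=0)
    order = counts.sum(axis=1).sort_values(ascending=False).index[:top_genes]
    counts = counts.loc[order]
    fig = Figure(figsize=(max(6, 0.25 * counts.shape[1] + 2), 0.3 * len(counts) + 1.5))
    ax = fig.add_subplot(111)
    ax.imshow(counts.to_numpy() > 0, aspect="auto", cmap="Reds", interpolation="nearest")
    ax.set_yticks(range(len(counts)), counts.index, fontsize=6)
    ax.set_xticks(range(counts.shape[1]), counts.columns, fontsize=5, rotation=90)
    ax.set_xlabel("sample")
    for i, g in enumerate(counts.index):
        ax.text(counts.shape[1] + 0.3, i, str(int(counts.loc[g].sum())), fontsize=6, va="center")
    ax.set_title("mutation landscape (accepted nonsynonymous calls)")
    _save(fig, path)


def signature_bars(signatures: np.ndarray, path) -> None:
    """One bar panel per signature over the 96 channels, COSMIC ordering."""
    signatures = np.atleast_2d(signatures)
    S = len(signatures)
    fig = Figure(figsize=(12, 2.2 * S))
    colors = [_SUB_COLORS[lab[2:5]] for lab in ch.CHANNELS_96]
    for k in range(S):
        ax = fig.add_subplot(S, 1, k + 1)
        ax.bar(range(96), signatures[k], color=colors, width=0.8)
        ax.set_ylabel(f"sig {k + 1}")
        ax.set_xlim(-1, 96)
        if k == S - 1:
            ax.set_xticks(range(96), ch.CHANNELS_96, rotation=90, fontsize=4)
        else:
            ax.set_xticks([])
    fig.suptitle("mutational signatures (96 trinucleotide channels)")
    _save(fig, path)


def recurrence_profile(markers: pd.DataFrame, path) -> None:
    """Amplification / deletion G-scores along the marker grid."""
    fig = Figure(figsize=(10, 3))
    ax = fig.add_subplot(111)
    x = np.arange(len(markers))
    ax.fill_between(x, markers["amp_gscore"], color="#E32926", alpha=0.7, label="amp G-score")
    ax.fill_between(x, -markers["del_gscore"], color="#3B6FB6", alpha=0.7, label="del G-score")
    bounds = markers["chrom"].ne(markers["chrom"].shift()).to_numpy().nonzero()[0]
    for b in bounds[1:]:
        ax.axvline(b, color="grey", lw=0.5)
    ax.set_xlabel("marker (genome order)")
    ax.set_ylabel("G-score")
    ax.legend(loc="upper right", fontsize=7)
    _save(fig, path)
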