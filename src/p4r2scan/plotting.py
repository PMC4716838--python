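"""Optional matplotlib figures (install the `plot` extra).

Display-only: stacked size-profile bars, end-offset histograms, and the
mismatch heat map. All functions take the corresponding analysis object
and write a PNG; nothing here feeds back into any statistic.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


BASE_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#b15928", "T": "#e31a1c"}


def plot_size_profile(profile: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Stacked bars of unique species per length, split by 5' base."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(9, 3.2))
    lengths = profile.index
    bottom = pd.Series(0, index=lengths)
    for base in "ACGT":
        if base not in profile.columns:
            continue
        ax.bar(lengths, profile[base], bottom=bottom, width=0.85,
               color=BASE_COLORS[base], label=f"5'-{base}")
        bottom = bottom + profile[base]
    ax.set_xlabel("RNA length (nt)")
    ax.set_ylabel("unique species")
    ax.set_xlim(14.5, 50.5)
    ax.legend(frameon=False, ncol=4, fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_offset_histogram(hist, path: str | Path, window: int = 15) -> None:
    plt = _plt()
    s = hist.to_series()
    s = s[(s.index >= -window) & (s.index <= window)]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(s.index, s.values, width=0.9, color="#444444")
    ax.set_xlabel(f"{'5prime' if hist.end == 'five_prime' else '3prime'} end offset (nt)")
    ax.set_ylabel("overlapping species pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mismatch_heatmap(matrix, path: str | Path, vmax: float | None = None) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(matrix.freq.values, aspect="auto", cmap="Reds",
                   vmin=0, vmax=vmax,
                   extent=[0.5, matrix.freq.columns.max() + 0.5,
                           matrix.freq.index.max() + 0.5, matrix.freq.index.min() - 0.5])
    ax.set_xlabel("read position (5'->3')")
    ax.set_ylabel("RNA length (nt)")
    fig.colorbar(im, ax=ax, label="% reads with mismatch")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
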