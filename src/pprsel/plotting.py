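"""Plots: window-scan profiles and partition omega bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_CLASS_COLORS = {
    "helixA": "#1f77b4",
    "helixB": "#ff7f0e",
    "coil": "#cccccc",
    "E": "#2ca02c",
    "E+": "#98df8a",
    "DYW": "#9467bd",
    "other": "#dddddd",
}


def plot_scan(results, pmap=None, path=None, gene_omega=None):
    """omega vs window midpoint nucleotide; undefined windows plot as gaps."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    xs = [r.midpoint_nt for r in results]
    ys = [r.omega if r.omega is not None else float("nan") for r in results]
    ax.plot(xs, ys, marker="o", ms=3, lw=1, color="black")
    if gene_omega is not None:
        ax.axhline(gene_omega, color="red", lw=0.8, ls="--", label="gene mean")
        ax.legend(frameon=False, fontsize=8)
    if pmap is not None:
        ymin = 0
        for e in pmap.entries:
            ax.axvspan(
                3 * (e.start_codon - 1) + 1,
                3 * e.end_codon,
                ymin=0.0,
                ymax=0.04,
                color=_CLASS_COLORS.get(e.structural_class, "#dddddd"),
            )
    ax.set_xlabel("midpoint nucleotide")
    ax.set_ylabel(r"$\omega$ (dN/dS)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_partition_bars(tests, gene_omega, path=None, alpha=0.05):
    """Per-partition omega estimates; significant partitions filled."""
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(tests)), 3.2))
    names = [t.partition_name for t in tests]
    omegas = [t.omega_hat for t in tests]
    colors = ["#d62728" if t.p_value < alpha else "#aaaaaa" for t in tests]
    ax.bar(range(len(tests)), omegas, color=colors)
    ax.axhline(gene_omega, color="black", lw=0.8, ls="--", label="gene mean")
    ax.set_xticks(range(len(tests)))
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel(r"$\omega$ (dN/dS)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
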