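"""Plot export: region scatterplots, delta-vs-heterozygote validation plots,
noise-reduction track panels and QC filtering curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["region_scatterplot", "delta_het_plot", "inspection_tracks",
           "qc_curve_plot"]

_CN_COLORS = {0: "#7b3294", 1: "#c2a5cf", 2: "#bdbdbd", 3: "#a6dba0", 4: "#008837"}


def _save(fig, path: str | Path) -> None:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def region_scatterplot(summaries: pd.DataFrame, genotypes: pd.DataFrame,
                       region_id: str, flank: str, path: str | Path) -> None:
    """Median target LRR (x) against median flank LRR (y), colored by the
    called copy number — satellite clusters sit left (deletions) or right
    (duplications) of the diploid cloud."""
    s = summaries[summaries["region_id"] == region_id]
    g = genotypes[genotypes["region_id"] == region_id][["sample_id", "cn"]]
    df = s.merge(g, on="sample_id", how="left")
    ycol = "median_flank5" if flank == "5prime" else "median_flank3"
    fig, ax = plt.subplots(figsize=(5, 4))
    for cn, grp in df.groupby("cn", dropna=False):
        color = _CN_COLORS.get(cn, "#d95f02")
        label = "no-call" if pd.isna(cn) else f"CN={int(cn)}"
        ax.scatter(grp["median_target"], grp[ycol], s=8, color=color, label=label)
    ax.set_xlabel("median target LRR")
    ax.set_ylabel(f"median {flank} flank LRR")
    ax.set_title(f"{region_id} ({flank})")
    ax.legend(fontsize=7, markerscale=2)
    _save(fig, path)


def delta_het_plot(table: pd.DataFrame, region_id: str, flank: str,
                   path: str | Path) -> None:
    """Delta against di-allelic and tri-allelic heterozygote counts: deletion
    clusters must sit at zero di-allelic hets, duplication clusters show
    tri-allelic hets."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True)
    for ax, col in zip(axes, ("n_di_het", "n_tri_het")):
        for cn, grp in table.groupby("cn", dropna=False):
            color = _CN_COLORS.get(cn, "#d95f02")
            ax.scatter(grp["delta"], grp[col], s=8, color=color)
        ax.set_xlabel("delta (LRR)")
        ax.set_ylabel(col)
    fig.suptitle(f"{region_id} ({flank}) BAF validation")
    _save(fig, path)


def inspection_tracks(positions: np.ndarray, query_lrr: np.ndarray,
                      reference_lrr: np.ndarray, corrected: np.ndarray,
                      target: tuple[int, int], sample_id: str,
                      reference_id: str, path: str | Path) -> None:
    """Raw, reference and difference LRR tracks over one chromosome with the
    candidate target highlighted — the pairwise wave-subtraction view."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    tracks = [(query_lrr, sample_id), (reference_lrr, f"reference {reference_id}"),
              (corrected, "difference (query - reference)")]
    for ax, (y, title) in zip(axes, tracks):
        ax.plot(positions / 1e6, y, ".", ms=1.5, color="#404040")
        ax.axvspan(target[0] / 1e6, target[1] / 1e6, color="#fdb863", alpha=0.4)
        ax.set_ylabel("LRR")
        ax.set_title(title, fontsize=9)
    axes[-1].set_xlabel("position (Mb)")
    _save(fig, path)


def qc_curve_plot(curves: pd.DataFrame, path: str | Path) -> None:
    """False-to-true ratio against exclusion fraction, per method and metric."""
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"penncnv_calls": ":", "lrr_variance": "--", "call_rate": "-"}
    colors = {"penncnv": "black", "scatterplot": "gray"}
    for (method, metric), grp in curves.groupby(["method", "metric"]):
        grp = grp.sort_values("exclude_fraction")
        ax.plot(grp["exclude_fraction"] * 100, grp["false_to_true"],
                styles.get(metric, "-"), color=colors.get(method, "C0"),
                label=f"{method} / {metric}")
    ax.set_xlabel("low-quality samples excluded (%)")
    ax.set_ylabel("false-to-true ratio")
    ax.legend(fontsize=7)
    _save(fig, path)
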