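"""Figure rendering: LRT profile plots and predicted-QTL-effect scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import GeneticMap
from .scan import CarrierContrast, ScanResult


def plot_lrt_profile(
    result: ScanResult,
    gmap: GeneticMap | None = None,
    contrast: ScanResult | None = None,
    causal_position: float | None = None,
    thresholds: dict[str, float] | None = None,
    path=None,
):
    """One linkage group's LRT profile; optionally overlays a carrier-exclusion
    scan, a vertical line at the causal position and threshold lines.
    Markers are drawn as ticks above the x-axis."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(result.positions, result.lrt, "r--" if contrast is not None else "b-",
            label="all animals" if contrast is not None else result.trait)
    if contrast is not None:
        ax.plot(contrast.positions, contrast.lrt, "b-", label="carriers excluded")
    if causal_position is not None:
        ax.axvline(causal_position, color="k", lw=0.8)
    for name, th in (thresholds or {}).items():
        ax.axhline(th, ls=":", lw=0.8, color="grey")
        ax.annotate(name, (result.positions[-1], th), fontsize=7, ha="right", va="bottom")
    if gmap is not None:
        g = gmap.group(result.group)
        ymax = np.nanmax(result.lrt) if np.any(np.isfinite(result.lrt)) else 1.0
        ax.plot(g.positions, np.full(len(g.positions), -0.03 * ymax), "b^", ms=5, clip_on=False)
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("LRT")
    ax.set_title(f"{result.trait} - group {result.group}")
    if contrast is not None:
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_contrast(contrast: CarrierContrast, gmap: GeneticMap | None = None, thresholds=None, path=None):
    return plot_lrt_profile(
        contrast.include,
        gmap=gmap,
        contrast=contrast.exclude,
        causal_position=contrast.locus_position,
        thresholds=thresholds,
        path=path,
    )


def plot_qtl_effects(
    effects: pd.Series,
    effects_y: pd.Series | None = None,
    genotype_classes: pd.Series | None = None,
    path=None,
):
    """Scatter of predicted per-individual QTL genotypic effects, coloured by
    causal genotype class (mutant-allele count) when known."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    x = effects
    y = effects_y if effects_y is not None else pd.Series(
        np.random.default_rng(0).uniform(-1, 1, len(effects)), index=effects.index
    )
    common = x.index.intersection(y.index)
    x, y = x[common], y[common]
    if genotype_classes is not None:
        styles = {0: ("o", "tab:green", "wild-type"), 1: ("^", "tab:blue", "heterozygote"), 2: ("s", "tab:red", "homozygous mutant")}
        gc = genotype_classes.reindex(common)
        for cls, (mk, col, lab) in styles.items():
            sel = gc == cls
            if sel.any():
                ax.scatter(x[sel], y[sel], marker=mk, c=col, s=18, label=lab, alpha=0.8)
        ax.legend(fontsize=8)
    else:
        ax.scatter(x, y, s=18, alpha=0.8)
    ax.set_xlabel(x.name or "predicted QTL effect")
    ax.set_ylabel((effects_y.name if effects_y is not None else "jitter"))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
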