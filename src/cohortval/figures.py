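"""Matplotlib renderings of the analysis results (PNG/SVG)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .trial import KMEstimate
from .validation import (
    CorrelationResult,
    DensityBandResult,
    QuadraticFormResult,
    ScatterPair,
)


def boxplot_figure(values_by_label: dict[str, np.ndarray], title: str):
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(values_by_label)
    ax.boxplot([values_by_label[k] for k in labels], tick_labels=labels)
    ax.set_title(title)
    fig.tight_layout()
    return fig

def scatter_matrix_figure(pairs: Sequence[ScatterPair]):
    k = len(pairs)
    ncols = min(k, 3)
    nrows = (k + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows),
                             squeeze=False)
    for ax in axes.ravel()[k:]:
        ax.set_axis_off()
    for pair, ax in zip(pairs, axes.ravel()):
        ax.scatter(pair.real[:, 0], pair.real[:, 1], s=8, alpha=0.6,
                   label="real")
        ax.scatter(pair.virtual[:, 0], pair.virtual[:, 1], s=8, alpha=0.6,
                   label="virtual")
        ax.set_xlabel(pair.x)
        ax.set_ylabel(pair.y)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig

def correlation_heatmap_figure(result: CorrelationResult):
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, matrix, title in zip(
        axes,
        (result.real_matrix, result.virtual_matrix, result.difference_matrix),
        ("real", "virtual", "virtual - real"),
    ):
        im = ax.imshow(matrix, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(result.variables)))
        ax.set_yticks(range(len(result.variables)))
        ax.set_xticklabels(result.variables, rotation=45, ha="right", fontsize=7)
        ax.set_yticklabels(result.variables, fontsize=7)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig

def quadratic_form_figure(result: QuadraticFormResult):
    """QQ plot of the two cohorts' quadratic forms plus their histograms
    with the chi-squared reference density overlaid."""
    fig, (ax_qq, ax_hist) = plt.subplots(1, 2, figsize=(10, 4))
    ax_qq.scatter(result.qq_pairs[:, 0], result.qq_pairs[:, 1], s=8)
    lim = float(result.qq_pairs.max()) if result.qq_pairs.size else 1.0
    ax_qq.plot([0, lim], [0, lim], color="gray", lw=1)
    ax_qq.set_xlabel("real quantiles")
    ax_qq.set_ylabel("virtual quantiles")
    ax_qq.set_title("QQ of standardized quadratic forms")

    edges = result.hist_bin_edges
    centers = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges)
    n_real = result.d_real.size
    n_virtual = result.d_virtual.size
    ax_hist.bar(centers, result.hist_counts_real / (n_real * widths),
                width=widths, alpha=0.5, label="real")
    ax_hist.bar(centers, result.hist_counts_virtual / (n_virtual * widths),
                width=widths, alpha=0.5, label="virtual")
    xs = np.linspace(edges[0], edges[-1], 200)
    ax_hist.plot(xs, stats.chi2.pdf(xs, result.df), color="black",
                 label=f"chi2(df={result.df})")
    ax_hist.set_title("quadratic-form histograms")
    ax_hist.legend(fontsize=8)
    fig.tight_layout()
    return fig

def density_band_figure(result: DensityBandResult):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.grid, result.band_lower, result.band_upper,
                    alpha=0.3, label=f"{result.level:.0%} bootstrap band")
    ax.plot(result.grid, result.density_virtual, label="virtual density")
    ax.plot(result.grid, result.density_real, label="real density")
    ax.set_xlabel(result.variable)
    ax.set_ylabel("density")
    ax.set_title(
        f"out-of-band fraction {result.outside_fraction:.3f}"
        + (" (deviation)" if result.deviation_detected else "")
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig

def km_figure(curves: dict[str, KMEstimate]):
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, km in curves.items():
        times = np.concatenate([[0.0], km.event_times])
        surv = np.concatenate([[1.0], km.survival])
        line, = ax.step(times, surv, where="post", label=label)
        if km.censoring_times.size:
            ax.plot(km.censoring_times,
                    [km.survival_at(t) for t in km.censoring_times],
                    "+", color=line.get_color())
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig

def frequency_figure(counts_by_group: dict[str, dict[str, int]], title: str):
    levels = sorted({lv for c in counts_by_group.values() for lv in c})
    x = np.arange(len(levels))
    width = 0.8 / max(len(counts_by_group), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (label, counts) in enumerate(counts_by_group.items()):
        ax.bar(x + i * width, [counts.get(lv, 0) for lv in levels],
               width=width, label=label)
    ax.set_xticks(x + width * (len(counts_by_group) - 1) / 2)
    ax.set_xticklabels(levels)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig

def save_figure(fig, path) -> str:
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
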