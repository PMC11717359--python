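"""Figure rendering: interaction heatmaps and spacing bar graphs.

Both renderers return the underlying plotted data (a DataFrame) so tests can
assert on values rather than pixels.
"""
from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spacing_scan import QUADRANTS
from .spacing_stats import InteractionMatrix, SpacingHistogram, SpacingTestResult

log = logging.getLogger(__name__)

__all__ = ["render_heatmap", "render_spacing_bars"]


def render_heatmap(
    matrix: InteractionMatrix, out, cap: float = 50.0
) -> pd.DataFrame | None:
    """Heatmap of -log10(E): primary libraries on x, secondary motifs on y.

    Values are capped at ``cap`` for display. Returns the plotted grid, or
    None (with a warning, writing nothing) for an empty matrix.
    """
    if not matrix.cells:
        log.warning("empty interaction matrix; heatmap skipped")
        return None
    grid = matrix.to_neglog10_frame(cap=cap)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(grid.columns) + 2), max(3, 0.3 * len(grid) + 2))
    )
    im = ax.imshow(grid.values, aspect="auto", cmap="Reds", vmin=0, vmax=cap)
    ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(grid.index)), grid.index, fontsize=7)
    ax.set_xlabel("primary motif (ChIP-seq library)")
    ax.set_ylabel("secondary motif (database)")
    fig.colorbar(im, ax=ax, label="-log10(E-value)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return grid


def render_spacing_bars(
    hist: SpacingHistogram,
    result: SpacingTestResult,
    out,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Quadrant-faceted per-gap bar chart; significant bins highlighted red.

    A bin is flagged when its own Bonferroni-adjusted binomial p-value beats
    ``alpha``. Returns the plotted table (quadrant, gap, count, significant).
    """
    from .spacing_stats import binom_bin_pvalue

    if hist.n == 0:
        raise ValueError("empty histogram")
    rows = []
    for quadrant in QUADRANTS:
        for gap in range(hist.max_gap + 1):
            k = hist.count(quadrant, gap)
            sig = False
            if k:
                p_adj = min(1.0, binom_bin_pvalue(k, hist.n, hist.n_bins) * hist.n_bins)
                sig = p_adj < alpha
            rows.append(
                {"quadrant": quadrant, "gap": gap, "count": k, "significant": sig}
            )
    table = pd.DataFrame(rows)

    fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True, sharey=True)
    for ax, quadrant in zip(axes.ravel(), QUADRANTS):
        sub = table[table.quadrant == quadrant]
        colors = np.where(sub.significant, "crimson", "steelblue")
        ax.bar(sub.gap, sub["count"], color=colors, width=1.0)
        ax.set_title(quadrant, fontsize=9)
        ax.set_xlabel("gap (bp)")
        ax.set_ylabel("windows")
    fig.suptitle(
        f"{hist.secondary_id}: best bin ({result.best_quadrant}, {result.best_gap} bp), "
        f"k={result.k}/{result.n}, adj. p={result.p_adj:.2e}"
    )
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return table
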