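"""Figure-style plots: annulus profiles, distance boxplots, spot maps."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import SpotDataset
from .distance import DistanceResult
from .radial import EnrichmentProfile, PermutationResult

__all__ = ["plot_enrichment_profile", "plot_distance_boxplots", "plot_spot_map"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 3.5))
    return ax


def plot_enrichment_profile(
    profile: EnrichmentProfile,
    null: Optional[PermutationResult] = None,
    ax=None,
    alpha: float = 0.05,
):
    """Bar plot of per-annulus normalized scores, with the null 95% band.

    Annuli whose p-value (center null if attached) is below ``alpha`` are
    marked with an asterisk.
    """
    ax = _get_ax(ax)
    n = profile.n_bins
    x = np.arange(1, n + 1)
    ax.bar(x, profile.norm_score, color="#4878a8", label="observed")
    if null is not None:
        lo, _, hi = null.null_quantiles()
        ax.fill_between(x, lo, hi, color="gray", alpha=0.3, label="null 95%")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    pvals = profile.p_center if profile.p_center is not None else (
        null.p_values if null is not None else None
    )
    if pvals is not None:
        for xi, (score, p) in enumerate(zip(profile.norm_score, pvals), start=1):
            if np.isfinite(p) and p <= alpha and np.isfinite(score):
                ax.text(xi, score, "*", ha="center", va="bottom", fontsize=12)
    ax.set_xticks(x, [f"c{i}" for i in x])
    ax.set_xlabel("annulus (inner to outer)")
    ax.set_ylabel("normalized gene-set score")
    ax.legend(loc="best", frameon=False)
    return ax


def plot_distance_boxplots(results: Sequence[DistanceResult], ax=None):
    """Boxplots (median, quartiles, 1.5 x IQR whiskers) of source distances."""
    ax = _get_ax(ax)
    data = [r.distances_um for r in results if r.n > 0]
    labels = [r.gene for r in results if r.n > 0]
    ax.boxplot(data, tick_labels=labels, whis=1.5, showfliers=False)
    ax.set_ylabel("distance to nearest source cell (µm)")
    return ax


def plot_spot_map(
    data: SpotDataset,
    values: Optional[np.ndarray] = None,
    ax=None,
    size: float = 12.0,
):
    """Scatter of spot positions colored by ``values`` (default: total counts)."""
    ax = _get_ax(ax)
    if values is None:
        values = data.counts.sum(axis=0)
    sc = ax.scatter(data.coords[:, 0], data.coords[:, 1], c=values, s=size, cmap="viridis")
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    import matplotlib.pyplot as plt

    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
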