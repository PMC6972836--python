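"""Uncertainty-aware ordination plots.

Four presentation modes for a fitted ordination:

* ``points``  — posterior-mean site coordinates, labelled by site number.
* ``cloud``   — all retained posterior draws of highlighted sites drawn as a
  light point cloud beneath the labels, conveying the full posterior spread.
* ``ellipses``— 95% HPD region boundaries (KDE contours or normal ellipses)
  around highlighted sites.
* ``anchored``— as above after anchoring a reference site at the origin, so
  positions read as distances from that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .posterior import PosteriorChains, anchor, hpd_region_2d

__all__ = ["PlotSpec", "plot_ordination"]

_CLOUD_COLORS = ["#bdbdbd", "#fcae91", "#9ecae1", "#a1d99b", "#cbc9e2", "#fdd0a2"]


@dataclass
class PlotSpec:
    """What to draw and where to write it."""

    mode: str = "points"  # points | cloud | ellipses | anchored
    highlighted_sites: List[int] = field(default_factory=list)
    level: float = 0.95
    anchor_site: Optional[int] = None
    output_path: Optional[str] = None
    region_method: str = "kde"
    max_cloud_points: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("points", "cloud", "ellipses", "anchored"):
            raise ValueError(f"unknown plot mode {self.mode!r}")
        if self.mode == "anchored" and self.anchor_site is None:
            raise ValueError("anchored mode requires anchor_site")


def plot_ordination(chains: PosteriorChains, spec: PlotSpec):
    """Render an ordination figure; returns (fig, ax) and saves if asked.

    The input chains are never mutated; identical inputs give identical
    output (no jitter is used).
    """
    ch = anchor(chains, spec.anchor_site) if spec.mode == "anchored" else chains
    Z = ch.draws["Z"]  # (m, n, q)
    if Z.shape[2] < 2:
        raise ValueError("ordination plots require q >= 2")
    means = Z.mean(axis=0)
    n = Z.shape[1]
    fig, ax = plt.subplots(figsize=(6, 6))

    highlighted = list(spec.highlighted_sites)
    if spec.mode in ("cloud", "ellipses", "anchored") and not highlighted:
        highlighted = [int(np.argmax(Z.var(axis=0).sum(axis=1)))]

    if spec.mode in ("cloud", "anchored"):
        for ci, site in enumerate(highlighted):
            pts = Z[:, site, :2]
            if pts.shape[0] > spec.max_cloud_points:
                step = pts.shape[0] // spec.max_cloud_points
                pts = pts[::step]
            ax.scatter(
                pts[:, 0], pts[:, 1], s=4, alpha=0.25,
                color=_CLOUD_COLORS[ci % len(_CLOUD_COLORS)], zorder=1,
            )
    if spec.mode == "ellipses":
        for ci, site in enumerate(highlighted):
            region = hpd_region_2d(Z[:, site, :2], spec.level, spec.region_method)
            color = _CLOUD_COLORS[ci % len(_CLOUD_COLORS)]
            if region["method"] == "kde":
                for poly in region["polygons"]:
                    ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1.2, zorder=1)
            elif region["method"] == "normal_ellipse":
                _draw_ellipse(ax, region, color)
            else:  # degenerate box fallback
                (l0, u0), (l1, u1) = region["box"]
                ax.plot([l0, u0, u0, l0, l0], [l1, l1, u1, u1, l1], color=color, lw=1.2)

    # site labels as numerals (1-based), the conventional ordination style
    for i in range(n):
        ax.text(
            means[i, 0], means[i, 1], str(i + 1),
            ha="center", va="center", fontsize=9, zorder=3,
        )
    if spec.mode == "anchored":
        ax.plot([0], [0], marker="+", color="black", ms=12, zorder=4)
    lim = np.abs(means[:, :2]).max() * 1.3 + 0.5
    for site in highlighted:
        lim = max(lim, float(np.abs(Z[:, site, :2]).max()) * 1.05)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("Latent dimension 1")
    ax.set_ylabel("Latent dimension 2")
    ax.set_aspect("equal")
    if spec.output_path:
        fig.savefig(spec.output_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig, ax


def _draw_ellipse(ax, region, color):
    from matplotlib.patches import Ellipse

    cov = region["cov"]
    evals, evecs = np.linalg.eigh(cov)
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    width, height = 2 * np.sqrt(evals[-1] * region["radius2"]), 2 * np.sqrt(evals[0] * region["radius2"])
    ax.add_patch(
        Ellipse(
            region["mean"], width, height, angle=angle,
            fill=False, edgecolor=color, lw=1.2, zorder=1,
        )
    )
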