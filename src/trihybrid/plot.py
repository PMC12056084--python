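"""Triangle plots: interclass heterozygosity against hybrid index.

The HWE-permissible region is bounded by the solid lines het = 2h and
het = 2 - 2h and the dashed curve het = 2h(1-h); individuals cannot fall
below the curve under random mating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .hwe import class_expectations

logger = logging.getLogger(__name__)

FORMATS = ("png", "svg", "pdf")


@dataclass
class PlotSpec:
    """Rendering options for :func:`triangle_plot`."""

    color_by: str = "population"  # or "perc_missing"
    fmt: str = "png"
    show_boundary: bool = True
    show_class_points: bool = False
    space_points: list[tuple[float, float]] | None = None
    point_size: float = 36.0

    def __post_init__(self) -> None:
        if self.color_by not in ("population", "perc_missing"):
            raise ParameterError(f"unknown color_by {self.color_by!r}")
        if self.fmt not in FORMATS:
            raise ParameterError(f"format must be one of {FORMATS}")


# Okabe-Ito colorblind-safe cycle
_PALETTE = (
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#000000",
)


def _draw_boundary(ax) -> None:
    x = np.linspace(0.0, 1.0, 256)
    ax.plot([0.0, 0.5], [0.0, 1.0], color="black", lw=1.2)
    ax.plot([0.5, 1.0], [1.0, 0.0], color="black", lw=1.2)
    ax.plot(x, 2.0 * x * (1.0 - x), color="black", lw=1.2, ls=(0, (4, 3)))


def triangle_plot(table: pd.DataFrame, spec: PlotSpec, path: str) -> None:
    """Render a triangle plot of a results table to ``path``.

    Rows with undefined hybrid index or heterozygosity are skipped (a count
    is logged); coordinates are plotted exactly as tabulated, without
    jitter, on fixed [0, 1] x [0, 1] axes.
    """
    defined = table.dropna(subset=["hybrid_index", "heterozygosity"])
    n_skipped = len(table) - len(defined)
    if defined.empty:
        raise InputError("every row has undefined estimates; nothing to plot")
    if n_skipped:
        logger.info("skipping %d rows with undefined estimates", n_skipped)

    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    if spec.space_points:
        pts = np.asarray(spec.space_points)
        ax.scatter(pts[:, 0], pts[:, 1], s=4, color="black", zorder=1)
    if spec.show_boundary:
        _draw_boundary(ax)
    if spec.color_by == "population":
        for k, (pop, grp) in enumerate(defined.groupby("pop", sort=True)):
            ax.scatter(
                grp["hybrid_index"], grp["heterozygosity"],
                s=spec.point_size, label=str(pop),
                color=_PALETTE[k % len(_PALETTE)],
                edgecolors="black", linewidths=0.4, zorder=3,
            )
        ax.legend(title="population", fontsize=8, loc="upper right",
                  bbox_to_anchor=(1.0, 1.0))
    else:
        sc = ax.scatter(
            defined["hybrid_index"], defined["heterozygosity"],
            s=spec.point_size, c=defined["perc_missing"],
            cmap="viridis", vmin=0.0, vmax=100.0,
            edgecolors="black", linewidths=0.4, zorder=3,
        )
        fig.colorbar(sc, ax=ax, label="% missing")
    if spec.show_class_points:
        for ce in class_expectations(4):
            ax.scatter([ce.hybrid_index], [ce.heterozygosity],
                       marker="D", s=40, facecolors="none",
                       edgecolors="grey", zorder=2)
            ax.annotate(ce.label, (ce.hybrid_index, ce.heterozygosity),
                        fontsize=6, color="grey",
                        xytext=(3, 3), textcoords="offset points")

    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("hybrid index")
    ax.set_ylabel("interclass heterozygosity")
    fig.tight_layout()
    # strip volatile metadata so identical inputs give identical vector files
    metadata = {"svg": {"Date": None}, "pdf": {"CreationDate": None}}.get(spec.fmt)
    with plt.rc_context({"svg.hashsalt": "trihybrid"}):
        fig.savefig(path, format=spec.fmt, dpi=150, metadata=metadata)
    plt.close(fig)
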