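"""Rendering of 2D fragment matrices and derived profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless rendering; deterministic output
import matplotlib.pyplot as plt
import numpy as np

from .errors import SignalDomainError
from .fragmatrix import FragMatrix
from .regions import RdnaLandmarks, to_display_coord

__all__ = ["PlotSpec", "render_2d"]


@dataclass(frozen=True)
class PlotSpec:
    """How to render a matrix: overlays, color scale, output target."""

    output: str
    landmark_overlay: bool = True
    color_scale: str = "linear"  # {"linear", "log"}
    cmap: str = "Blues"
    dpi: int = 120
    title: Optional[str] = None

    def __post_init__(self) -> None:
        if self.color_scale not in ("linear", "log"):
            raise ValueError(f"unknown color scale {self.color_scale!r}")


def render_2d(
    matrix: FragMatrix,
    landmarks: Optional[RdnaLandmarks] = None,
    spec: Optional[PlotSpec] = None,
    nucleosome_dyads: Optional[list[int]] = None,
) -> str:
    """Render position (x, 1-based) vs fragment length (y) with intensity
    proportional to depth; optional landmark glyphs (rARS arrow, Reb1 box,
    5S box, nucleosome dyad markers).  Returns the output path."""
    if spec is None:
        raise ValueError("a PlotSpec with an output path is required")
    if matrix.counts.size == 0 or matrix.counts.max() <= 0:
        raise SignalDomainError("refusing to render an empty matrix")

    data = matrix.counts.T  # rows = length, cols = position
    if spec.color_scale == "log":
        data = np.log1p(data)
    x0 = float(to_display_coord(matrix.window.start))
    extent = (
        x0 - 0.5,
        x0 + matrix.pos_bin * matrix.n_pos - 0.5,
        matrix.len_min - 0.5,
        matrix.len_min + matrix.len_bin * matrix.n_len - 0.5,
    )
    fig, ax = plt.subplots(figsize=(9, 3.6))
    ax.imshow(
        data,
        origin="lower",
        aspect="auto",
        interpolation="nearest",
        cmap=spec.cmap,
        extent=extent,
    )
    ax.set_xlabel(f"{matrix.window.chrom} position (bp)")
    ax.set_ylabel("fragment length (bp)")
    if spec.title:
        ax.set_title(spec.title)

    if spec.landmark_overlay and landmarks is not None:
        rars_x = to_display_coord(landmarks.rars)
        ax.axvline(rars_x, color="red", lw=0.8, ls="--")
        ax.annotate(
            "rARS", (rars_x, extent[3]), xytext=(rars_x, extent[3] - 12),
            color="red", ha="center", fontsize=8,
            arrowprops={"arrowstyle": "-|>", "color": "red"},
        )
        ax.axvspan(
            to_display_coord(landmarks.reb1_site.start), landmarks.reb1_site.end,
            color="gray", alpha=0.3, lw=0,
        )
        ax.axvspan(
            to_display_coord(landmarks.five_s.start), landmarks.five_s.end,
            color="purple", alpha=0.2, lw=0,
        )
        if nucleosome_dyads:
            ax.plot(
                [to_display_coord(d) for d in nucleosome_dyads],
                [matrix.len_max - 10] * len(nucleosome_dyads),
                "o", color="steelblue", ms=5, mec="none", alpha=0.8,
            )
    fig.tight_layout()
    out = Path(spec.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    # strip creation metadata so identical inputs give identical bytes
    savefig_kwargs = {"dpi": spec.dpi}
    if out.suffix.lower() == ".png":
        savefig_kwargs["metadata"] = {"Software": None}
    elif out.suffix.lower() == ".svg":
        savefig_kwargs["metadata"] = {"Date": None}
    fig.savefig(out, **savefig_kwargs)
    plt.close(fig)
    return str(out)
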