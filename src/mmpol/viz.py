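"""Rendering of anisotropy line-segment maps to raster images.

Each defined block is drawn as a line segment through its center,
oriented by the block's slow-axis circular mean, with length scaled by
``1 - circular variance`` (uniform blocks draw long lines, dispersed
blocks short ones); omitted blocks draw nothing.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_anisotropy_map"]


def render_anisotropy_map(
    table: pd.DataFrame,
    block_px: int,
    background: np.ndarray | None = None,
    path: str | Path | None = None,
    dpi: int = 150,
):
    """Render a :func:`~mmpol.anisotropy.make_anisotropy_map` table.

    Parameters
    ----------
    table
        Block table with ``row_px, col_px, mean_axis_rad, line_length,
        omitted`` columns.
    block_px
        Block edge length in pixels (sets segment scale).
    background
        Optional grayscale image (e.g. a retardance map) drawn under
        the segments.
    path
        Output raster path (PNG etc.); when None the figure is returned
        without saving.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background, cmap="gray", interpolation="nearest")
    for _, blk in table.iterrows():
        if blk.get("omitted", False) or not np.isfinite(blk["mean_axis_rad"]):
            continue
        cy = blk["row_px"] + block_px / 2
        cx = blk["col_px"] + block_px / 2
        half = 0.5 * block_px * float(blk["line_length"])
        # image rows grow downward, so a positive (counterclockwise)
        # axis angle maps to a negative row offset
        dx, dy = half * np.cos(blk["mean_axis_rad"]), -half * np.sin(blk["mean_axis_rad"])
        ax.plot([cx - dx, cx + dx], [cy - dy, cy + dy], color="tab:red", lw=1.5)
    ax.set_aspect("equal")
    ax.set_xlabel("column (px)")
    ax.set_ylabel("row (px)")
    if path is not None:
        fig.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        return Path(path)
    return fig
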