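"""Lesion-probability heat maps over the tile grid.

Each kept tile of a slide is painted with a colormap at its MIL patch
probability; tiles absent from the manifest (background, filtered) stay
transparent, so the overlay can be composited on the slide thumbnail to
show where the model believes lesion tissue lies.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .mil import PatchScore
from .tiling import TileManifest, TILE_SIZE


class HeatmapError(ValueError):
    pass


def heatmap_grid(scores: list[PatchScore], manifest: TileManifest) -> np.ma.MaskedArray:
    """Probabilities on the tile grid; tiles without a score are masked."""
    grid = np.ma.masked_all((manifest.grid_rows, manifest.grid_cols))
    kept = {(t.row, t.col) for t in manifest.kept_tiles}
    for s in scores:
        if (s.ref.row, s.ref.col) not in kept:
            raise HeatmapError(f"score ref ({s.ref.row},{s.ref.col}) outside manifest")
        if not 0.0 <= s.p_lesion <= 1.0:
            raise HeatmapError(f"p_lesion {s.p_lesion} outside [0,1]")
        grid[s.ref.row, s.ref.col] = s.p_lesion
    return grid


def render_heatmap(scores: list[PatchScore], manifest: TileManifest,
                   colormap: str = "jet", alpha: float = 0.6,
                   block: int = TILE_SIZE) -> np.ndarray:
    """RGBA uint8 overlay; tile (row, col) maps to pixel block (row, col).

    `block` sets the rendered pixels per tile (default full 224; use a
    smaller value for thumbnails).
    """
    grid = heatmap_grid(scores, manifest)
    cmap = colormaps[colormap]
    rgba = cmap(grid.filled(0.0))  # (rows, cols, 4) float
    rgba[..., 3] = np.where(grid.mask, 0.0, alpha)
    out = np.kron(rgba, np.ones((block, block, 1)))
    return np.rint(out * 255).astype(np.uint8)


def composite(base_rgb: np.ndarray, overlay_rgba: np.ndarray) -> np.ndarray:
    """Alpha-blend the heat-map overlay onto a slide thumbnail."""
    if base_rgb.shape[:2] != overlay_rgba.shape[:2]:
        raise HeatmapError("base and overlay dimensions differ")
    a = overlay_rgba[..., 3:4] / 255.0
    out = base_rgb.astype(float) * (1 - a) + overlay_rgba[..., :3].astype(float) * a
    return np.rint(out).astype(np.uint8)
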