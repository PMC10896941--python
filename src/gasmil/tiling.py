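"""Grid slides into non-overlapping 224x224 tiles at fixed resolutions.

A slide raster is rescaled to a target resolution in microns-per-pixel (MPP),
gridded row-major from the top-left corner, and incomplete edge tiles are
dropped so every tile honours the 224x224 contract. Tiles at the fine scale
(0.5 MPP) are linked to the coarse scale (2.0 MPP) through `parent_tile`,
which maps each fine tile to the coarse tile covering the same physical
position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.measure import block_reduce
from skimage.transform import resize

TILE_SIZE = 224
SCALES = (0.5, 2.0)  # µm per pixel: ~20x and ~5x magnification


class TilingError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class TileRef:
    """A tile's position on one slide's grid at one resolution."""

    slide_id: str
    mpp: float
    row: int
    col: int

    @property
    def origin_px(self) -> tuple[int, int]:
        return (self.row * TILE_SIZE, self.col * TILE_SIZE)


@dataclass
class Patch:
    ref: TileRef
    pixels: np.ndarray  # (224, 224, 3) uint8

    def __post_init__(self):
        if self.pixels.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise TilingError(f"patch must be {TILE_SIZE}x{TILE_SIZE}x3, got {self.pixels.shape}")


@dataclass
class TileManifest:
    slide_id: str
    mpp: float
    grid_rows: int
    grid_cols: int
    kept_tiles: list[TileRef] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "slide_id": self.slide_id,
            "mpp": self.mpp,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "kept_tiles": [[t.row, t.col] for t in self.kept_tiles],
            "provenance": self.provenance,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TileManifest":
        d = json.loads(text)
        tiles = [TileRef(d["slide_id"], d["mpp"], r, c) for r, c in d["kept_tiles"]]
        return cls(d["slide_id"], d["mpp"], d["grid_rows"], d["grid_cols"], tiles, d["provenance"])


def rescale_to_mpp(image: np.ndarray, native_mpp: float, target_mpp: float) -> np.ndarray:
    """Downsample `image` from native_mpp to target_mpp with area averaging."""
    if native_mpp > target_mpp:
        raise TilingError(
            f"cannot upsample: native {native_mpp} MPP is coarser than target {target_mpp} MPP"
        )
    if native_mpp == target_mpp:
        return image
    factor = target_mpp / native_mpp
    if abs(factor - round(factor)) < 1e-9:
        f = int(round(factor))
        h, w = (image.shape[0] // f) * f, (image.shape[1] // f) * f
        out = block_reduce(image[:h, :w].astype(np.float64), (f, f, 1), np.mean)
    else:
        h = int(image.shape[0] / factor)
        w = int(image.shape[1] / factor)
        out = resize(image.astype(np.float64), (h, w, 3), anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def tile_slide(
    image: np.ndarray,
    native_mpp: float,
    target_mpp: float,
    slide_id: str = "slide",
    tile_size: int = TILE_SIZE,
    tissue_filter: bool = True,
    s_min: float = 0.05,
    v_max: float = 250.0,
    t_frac: float = 0.1,
) -> tuple[TileManifest, list[Patch]]:
    """Rescale to `target_mpp`, grid row-major, drop incomplete edge tiles.

    Raises if the image metadata lacks a resolution or the rescaled image is
    smaller than one tile. When `tissue_filter` is set, tiles failing the HSV
    tissue criterion are excluded from the manifest.
    """
    if native_mpp is None or not np.isfinite(native_mpp) or native_mpp <= 0:
        raise TilingError("native MPP metadata missing or invalid; refusing to guess")
    img = rescale_to_mpp(np.asarray(image), native_mpp, target_mpp)
    rows, cols = img.shape[0] // tile_size, img.shape[1] // tile_size
    if rows < 1 or cols < 1:
        raise TilingError(
            f"image {img.shape[:2]} at {target_mpp} MPP is smaller than one {tile_size}px tile"
        )
    cfg = f"tile_size={tile_size};s_min={s_min};v_max={v_max};t_frac={t_frac};filter={tissue_filter}"
    manifest = TileManifest(
        slide_id=slide_id,
        mpp=target_mpp,
        grid_rows=rows,
        grid_cols=cols,
        provenance={"tiler_config_sha1": hashlib.sha1(cfg.encode()).hexdigest()},
    )
    patches: list[Patch] = []
    for r in range(rows):
        for c in range(cols):
            px = img[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size]
            patch = Patch(TileRef(slide_id, target_mpp, r, c), px)
            if tissue_filter and not filter_tissue(patch, s_min, v_max, t_frac):
                continue
            manifest.kept_tiles.append(patch.ref)
            patches.append(patch)
    return manifest, patches


def filter_tissue(patch: Patch, s_min: float = 0.05, v_max: float = 250.0,
                  t_frac: float = 0.1) -> bool:
    """Keep a tile if >= t_frac of its pixels look like stained tissue.

    A pixel counts as tissue when its HSV saturation exceeds `s_min` (scale
    0-1) and its value is below `v_max` (scale 0-255); glass background is
    bright and unsaturated.
    """
    hsv = rgb2hsv(patch.pixels)
    tissue = (hsv[..., 1] > s_min) & (hsv[..., 2] * 255.0 < v_max)
    return float(tissue.mean()) >= t_frac


def parent_tile(child: TileRef, parent_mpp: float = 2.0) -> TileRef:
    """Map a fine-scale tile to the coarse tile covering the same position."""
    ratio = parent_mpp / child.mpp
    if abs(ratio - round(ratio)) > 1e-9:
        raise TilingError(f"scale ratio {ratio} is not integral")
    r = int(round(ratio))
    return TileRef(child.slide_id, parent_mpp, child.row // r, child.col // r)


def harmonize_scales(children: list[TileRef], parents: list[TileRef],
                     parent_mpp: float = 2.0) -> list[TileRef]:
    """Drop fine tiles whose coarse parent is absent (e.g. filtered out)."""
    have = {(p.row, p.col) for p in parents}
    return [c for c in children
            if (parent_tile(c, parent_mpp).row, parent_tile(c, parent_mpp).col) in have]


# -- workspace I/O -------------------------------------------------------


def save_tiles(workspace: Path, manifest: TileManifest, patches: list[Patch]) -> None:
    base = Path(workspace) / manifest.slide_id / str(manifest.mpp)
    base.mkdir(parents=True, exist_ok=True)
    for p in patches:
        Image.fromarray(p.pixels).save(base / f"{p.ref.row}_{p.ref.col}.png")
    mdir = Path(workspace) / manifest.slide_id
    (mdir / f"manifest_{manifest.mpp}.json").write_text(manifest.to_json())


def load_tiles(workspace: Path, slide_id: str, mpp: float) -> tuple[TileManifest, list[Patch]]:
    mpath = Path(workspace) / slide_id / f"manifest_{mpp}.json"
    manifest = TileManifest.from_json(mpath.read_text())
    patches = []
    for ref in manifest.kept_tiles:
        img = Image.open(Path(workspace) / slide_id / str(mpp) / f"{ref.row}_{ref.col}.png")
        patches.append(Patch(ref, np.asarray(img)[..., :3]))
    return manifest, patches


def read_pyramidal_tiff(path: Path, level: int = 0) -> tuple[np.ndarray, float | None]:
    """Optional adapter: read a (pyramidal) TIFF page and its MPP if stored."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[level]
        arr = page.asarray()
        mpp = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None and getattr(unit, "value", None) is not None:
            num, den = res.value
            if num:
                unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
                if unit_um:
                    mpp = unit_um * den / num
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3], mpp
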