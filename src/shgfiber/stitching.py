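"""Mosaic assembly of overlapping quadrant tile scans.

Whole tissue sections larger than one acquisition footprint are scanned as
square quadrants with ~300 um of overlap between neighbours.  Each tile comes
with a nominal stage origin; the true offset is refined by maximising the
normalized cross-correlation (NCC) of the overlap region over a bounded
integer search window, and overlapping voxels are blended with a maximum —
SHG signal is sparse-bright on dark, so max blending avoids seam dimming and
is idempotent when crops agree.

Coordinates are row-major (y, x), origin top-left, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import ShgImage, read_tiff

#: Nominal tile overlap, um.
DEFAULT_OVERLAP_UM = 300.0

#: In-plane sampling of tiled scans, um per pixel.
DEFAULT_TILE_PIXEL_SIZE_UM = 0.53

MIN_OVERLAP_PX = 32


@dataclass
class Tile:
    """One tile image and its nominal (y, x) origin in mosaic pixels."""

    image: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("tiles must be 2D")
        self.origin = (int(self.origin[0]), int(self.origin[1]))


@dataclass
class TileLayout:
    """A set of tiles with nominal origins and shared pixel size."""

    tiles: list[Tile]
    overlap_um: float = DEFAULT_OVERLAP_UM
    pixel_size_um: float = DEFAULT_TILE_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("layout has no tiles")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def load_layout(path, pixel_size_um: float = DEFAULT_TILE_PIXEL_SIZE_UM) -> TileLayout:
    """Read a JSON layout: a list of ``{"path": ..., "y_px": ..., "x_px": ...}``."""
    with open(path) as fh:
        entries = json.load(fh)
    tiles = [
        Tile(read_tiff(e["path"]).intensities, (e["y_px"], e["x_px"])) for e in entries
    ]
    return TileLayout(tiles, pixel_size_um=pixel_size_um)


def _overlap_patches(a: np.ndarray, b: np.ndarray, shift: tuple[int, int]):
    """Aligned overlap patches of ``a`` at (0,0) and ``b`` at ``shift``."""
    sy, sx = shift
    ys, ye = max(0, sy), min(a.shape[0], sy + b.shape[0])
    xs, xe = max(0, sx), min(a.shape[1], sx + b.shape[1])
    if ye - ys <= 0 or xe - xs <= 0:
        return None, None
    return a[ys:ye, xs:xe], b[ys - sy : ye - sy, xs - sx : xe - sx]


def _ncc(pa: np.ndarray, pb: np.ndarray) -> float:
    da = pa - pa.mean()
    db = pb - pb.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        return np.nan
    return float((da * db).sum() / denom)


def refine_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_shift: tuple[int, int],
    search_radius_px: int = 20,
    min_score: float = 0.30,
) -> tuple[tuple[int, int], float]:
    """Refine the integer shift of ``tile_b`` relative to ``tile_a``.

    Scans every integer shift within ``search_radius_px`` of the nominal and
    returns the one maximising the NCC of the overlap, together with the
    score.  Ties prefer the candidate closest to the nominal.

    Raises if the nominal overlap is under 32 px in either dimension.  A flat
    (zero-variance) or uncorrelated overlap (best NCC below ``min_score``,
    e.g. pure noise) falls back to the nominal shift with score 0 and a
    warning.
    """
    tile_a = np.asarray(tile_a, dtype=float)
    tile_b = np.asarray(tile_b, dtype=float)
    ny, nx = int(nominal_shift[0]), int(nominal_shift[1])
    pa, pb = _overlap_patches(tile_a, tile_b, (ny, nx))
    if pa is None or min(pa.shape) < MIN_OVERLAP_PX:
        raise ValueError("nominal overlap is smaller than 32 px in some dimension")
    if pa.std() == 0 or pb.std() == 0:
        warnings.warn("flat overlap region; keeping the nominal shift")
        return (ny, nx), 0.0

    best_score, best_shift, best_dist = -np.inf, (ny, nx), 0.0
    for dy in range(-search_radius_px, search_radius_px + 1):
        for dx in range(-search_radius_px, search_radius_px + 1):
            cand = (ny + dy, nx + dx)
            pa, pb = _overlap_patches(tile_a, tile_b, cand)
            if pa is None or pa.size < MIN_OVERLAP_PX**2:
                continue
            score = _ncc(pa, pb)
            if np.isnan(score):
                continue
            dist = dy * dy + dx * dx
            if score > best_score or (score == best_score and dist < best_dist):
                best_score, best_shift, best_dist = score, cand, dist
    if not np.isfinite(best_score) or best_score < min_score:
        warnings.warn(
            f"no credible correlation peak (best NCC {best_score:.3f}); "
            "keeping the nominal shift"
        )
        return (ny, nx), 0.0
    return best_shift, best_score


def stitch(
    layout: TileLayout,
    search_radius_px: int = 20,
    refine: bool = True,
) -> ShgImage:
    """Assemble a mosaic from a tile layout.

    The first tile anchors the mosaic at its nominal origin.  Every other
    tile is registered against the already-placed tile it nominally overlaps
    the most (NCC refinement within ``search_radius_px``; ``refine=False``
    trusts the stage coordinates).  The canvas is the union of refined tile
    footprints; overlap voxels take the maximum across contributing tiles.
    """
    tiles = layout.tiles
    positions: dict[int, tuple[int, int]] = {0: tiles[0].origin}
    remaining = list(range(1, len(tiles)))

    def nominal_overlap_area(i: int, j: int) -> int:
        oy = min(
            tiles[i].origin[0] + tiles[i].image.shape[0],
            tiles[j].origin[0] + tiles[j].image.shape[0],
        ) - max(tiles[i].origin[0], tiles[j].origin[0])
        ox = min(
            tiles[i].origin[1] + tiles[i].image.shape[1],
            tiles[j].origin[1] + tiles[j].image.shape[1],
        ) - max(tiles[i].origin[1], tiles[j].origin[1])
        return max(oy, 0) * max(ox, 0)

    while remaining:
        # next tile: the one with the largest nominal overlap with a placed tile
        best = max(
            ((i, j) for i in remaining for j in positions),
            key=lambda ij: nominal_overlap_area(*ij),
        )
        i, j = best
        if nominal_overlap_area(i, j) == 0:
            raise ValueError(f"tile {i} overlaps no placed tile at nominal origins")
        nominal_rel = (
            tiles[i].origin[0] - tiles[j].origin[0],
            tiles[i].origin[1] - tiles[j].origin[1],
        )
        if refine:
            rel, _ = refine_offset(
                tiles[j].image, tiles[i].image, nominal_rel, search_radius_px
            )
        else:
            rel = nominal_rel
        positions[i] = (positions[j][0] + rel[0], positions[j][1] + rel[1])
        remaining.remove(i)

    min_y = min(p[0] for p in positions.values())
    min_x = min(p[1] for p in positions.values())
    max_y = max(positions[i][0] + tiles[i].image.shape[0] for i in positions)
    max_x = max(positions[i][1] + tiles[i].image.shape[1] for i in positions)
    canvas = np.zeros((max_y - min_y, max_x - min_x), dtype=float)
    for i, (py, px) in positions.items():
        h, w = tiles[i].image.shape
        y0, x0 = py - min_y, px - min_x
        region = canvas[y0 : y0 + h, x0 : x0 + w]
        np.maximum(region, tiles[i].image, out=region)
    return ShgImage(canvas, pixel_size_um=layout.pixel_size_um)
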