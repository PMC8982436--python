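"""Cell lattice: a planar epithelial strip as a Voronoi tessellation.

The blastoderm surface is modeled as a 2-D strip of cells. Centers sit on a
hexagonal lattice (alternate rows offset by half a pitch, vertical pitch
= cell_pitch * sqrt(3)/2), optionally jittered, and every pixel is assigned
to its nearest center. The x axis is treated periodically when measuring
distance to centers, so at zero jitter every cell is congruent and the
tessellation tiles the strip exactly; the raster itself is not wrapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, box
from skimage import measure

from ..config import ConfigError, SimConfig, rng_for

ROW_PITCH_FACTOR = math.sqrt(3.0) / 2.0


@dataclass
class CellMap:
    """Segmented synthetic tissue: label raster plus per-cell geometry.

    ``cells`` has one row per cell: label (1..n), cx, cy (pixel coordinates,
    x = column), area_px, dv (normalized row position in [0, 1]), border
    (touches the image edge).
    """

    label_image: np.ndarray
    cells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    def polygon(self, label: int) -> np.ndarray:
        """Boundary polygon of one cell as an (n, 2) array of (y, x) vertices."""
        mask = self.label_image == label
        if not mask.any():
            raise KeyError(f"no cell with label {label}")
        padded = np.pad(mask, 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        longest = max(contours, key=len)
        return longest - 1.0  # undo padding offset

    def border_labels(self) -> np.ndarray:
        return self.cells.loc[self.cells["border"], "label"].to_numpy()


def lattice_centers(config: SimConfig) -> tuple[np.ndarray, int, int]:
    """Jittered hexagonal centers and the strip's (height, width) in pixels."""
    pitch = float(config.cell_pitch_px)
    width = int(round(config.n_cols * pitch))
    height = max(1, int(round(config.n_rows * pitch * ROW_PITCH_FACTOR)))
    row_pitch = height / config.n_rows
    rng = rng_for(config.seed, 0)
    centers = np.empty((config.n_rows * config.n_cols, 2))  # (x, y)
    k = 0
    for r in range(config.n_rows):
        y = (r + 0.5) * row_pitch
        for i in range(config.n_cols):
            x = ((i + 0.5 + 0.5 * (r % 2)) * pitch) % width
            centers[k] = (x, y)
            k += 1
    if config.jitter > 0:
        centers += rng.uniform(-config.jitter, config.jitter, centers.shape) * pitch
        centers[:, 0] %= width
        centers[:, 1] = np.clip(centers[:, 1], 0.0, height - 1e-9)
    return centers, height, width


def _voronoi_areas(centers: np.ndarray, height: int, width: int):
    """Exact geometric area of each cell's Voronoi region clipped to the
    strip, honoring x-periodicity (a wrapped cell's two pieces sum).

    Returns None for degenerate geometries (e.g. a single center), where
    the caller falls back to pixel counts.
    """
    n = len(centers)
    if n < 2:
        return None
    reps = np.concatenate(
        [centers, centers + [width, 0], centers - [width, 0]], axis=0
    )
    strip = box(0, 0, width, height)
    try:
        cells = shapely.voronoi_polygons(
            MultiPoint(reps), extend_to=strip.buffer(width))
    except Exception:
        return None
    polys = list(cells.geoms)
    if len(polys) != len(reps):
        return None
    # voronoi_polygons does not preserve input order: match polygon -> generator
    tree = shapely.STRtree(polys)
    areas = np.zeros(n)
    pts = shapely.points(reps)
    idx_poly = tree.query(pts, predicate="within")
    owner = np.full(len(reps), -1)
    owner[idx_poly[0]] = idx_poly[1]
    if (owner < 0).any():
        return None
    for gen_i, poly_i in enumerate(owner):
        piece = polys[poly_i].intersection(strip)
        if not piece.is_empty:
            areas[gen_i % n] += piece.area
    return areas


def build_cell_lattice(config: SimConfig) -> CellMap:
    """Tessellate the strip into cells around jittered hexagonal centers.

    Returns a :class:`CellMap` whose labels are contiguous from 1 in
    row-major center order. DV coordinate is the center's normalized y.
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("build_cell_lattice expects a SimConfig")
    centers, height, width = lattice_centers(config)
    n = len(centers)
    # periodic in x: replicate centers shifted by +-width, query nearest
    reps = np.concatenate(
        [centers, centers + [width, 0], centers - [width, 0]], axis=0
    )
    tree = cKDTree(reps)
    yy, xx = np.mgrid[0:height, 0:width]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    _, idx = tree.query(pts, k=1)
    labels = (idx % n).astype(np.int32).reshape(height, width) + 1

    areas = _voronoi_areas(centers, height, width)
    if areas is None:  # degenerate geometry: fall back to pixel counts
        areas = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(float)
    border = np.zeros(n, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border[np.unique(edge) - 1] = True
    cells = pd.DataFrame(
        {
            "label": np.arange(1, n + 1, dtype=np.int32),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "area_px": areas,
            "dv": centers[:, 1] / height,
            "border": border,
        }
    )
    if (areas == 0).any():
        # extreme jitter can in principle starve a cell of pixels; relabel
        keep = areas > 0
        old = cells.loc[keep].reset_index(drop=True)
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[old["label"].to_numpy()] = np.arange(1, keep.sum() + 1)
        labels = remap[labels]
        old["label"] = np.arange(1, keep.sum() + 1, dtype=np.int32)
        cells = old
    return CellMap(label_image=labels, cells=cells)
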