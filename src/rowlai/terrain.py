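"""Bare-earth terrain modeling and point-height normalization.

The digital terrain model (DTM) is gridded from a pre-planting bare-earth
acquisition and held fixed for the whole season; canopy-epoch heights are
the per-point difference to the DTM cell. Points below a 10 cm height
threshold are classified as ground, everything at or above it as
vegetation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pointcloud import PointCloud

__all__ = [
    "TerrainModel",
    "HeightCloud",
    "build_dtm",
    "normalize_heights",
    "GROUND_THRESHOLD",
    "DEFAULT_CELL_SIZE",
]

#: Height below which a normalized point counts as ground (m).
GROUND_THRESHOLD = 0.10

#: Default DTM cell size (m); resolves the ~0.76 m row spacing.
DEFAULT_CELL_SIZE = 0.25


@dataclass
class TerrainModel:
    """Gridded bare-earth elevation.

    ``elevation[i, j]`` is the cell with lower-left corner at
    ``(x0 + j*cell_size, y0 + i*cell_size)`` — row index increases with y.
    After construction every cell holds a finite elevation (empty cells
    are nearest-neighbor filled).
    """

    origin: tuple[float, float]
    cell_size: float
    elevation: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.elevation = np.atleast_2d(np.asarray(self.elevation, dtype=float))
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.elevation.size == 0:
            raise ValueError("elevation grid must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point, clamped to the grid."""
        nrows, ncols = self.shape
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return np.clip(row, 0, nrows - 1), np.clip(col, 0, ncols - 1)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Terrain elevation under each (x, y); outside points clamp to the
        nearest cell rather than erroring (plot polygons may slightly
        exceed the flight footprint)."""
        row, col = self.cell_index(x, y)
        return self.elevation[row, col]

    def to_ascii(self, path: str | Path) -> None:
        """Export as an ESRI ASCII raster (rows written north to south)."""
        nrows, ncols = self.shape
        lines = [
            f"ncols {ncols}",
            f"nrows {nrows}",
            f"xllcorner {self.origin[0]:.6f}",
            f"yllcorner {self.origin[1]:.6f}",
            f"cellsize {self.cell_size:.6f}",
            f"NODATA_value {self.nodata:.1f}",
        ]
        for row in self.elevation[::-1]:
            lines.append(" ".join(f"{v:.4f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "TerrainModel":
        text = Path(path).read_text(encoding="utf-8").strip().splitlines()
        head = {}
        for line in text[:6]:
            key, val = re.split(r"\s+", line.strip(), maxsplit=1)
            head[key.lower()] = float(val)
        grid = np.loadtxt(text[6:], ndmin=2)[::-1]
        return cls(
            origin=(head["xllcorner"], head["yllcorner"]),
            cell_size=head["cellsize"],
            elevation=grid,
            nodata=head.get("nodata_value", -9999.0),
        )


@dataclass
class HeightCloud:
    """A point cloud with per-point height above terrain and ground flag."""

    cloud: PointCloud
    height: np.ndarray
    is_ground: np.ndarray
    ground_threshold: float = GROUND_THRESHOLD

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.is_ground = np.asarray(self.is_ground, dtype=bool)
        if not (self.height.shape == self.is_ground.shape == (self.cloud.n,)):
            raise ValueError("height/class arrays must match point count")

    @property
    def n_ground(self) -> int:
        return int(self.is_ground.sum())

    @property
    def n_vegetation(self) -> int:
        return int((~self.is_ground).sum())

    @property
    def vegetation_heights(self) -> np.ndarray:
        return self.height[~self.is_ground]

    def take(self, index: np.ndarray) -> "HeightCloud":
        return HeightCloud(
            self.cloud.take(index),
            self.height[index],
            self.is_ground[index],
            self.ground_threshold,
        )


def build_dtm(bare_earth: PointCloud, cell_size: float = DEFAULT_CELL_SIZE) -> TerrainModel:
    """Grid a bare-earth cloud into a DTM.

    Each cell takes the MINIMUM z of its points — robust to low vegetation
    and debris in the pre-planting acquisition. Cells without points are
    filled from the nearest populated cell, so the returned grid has no
    no-data holes. The grid covers the point bounding box.
    """
    if bare_earth.n == 0:
        raise ValueError("no terrain points")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    x0, y0 = float(bare_earth.x.min()), float(bare_earth.y.min())
    ncols = max(1, int(np.ceil((bare_earth.x.max() - x0) / cell_size)))
    nrows = max(1, int(np.ceil((bare_earth.y.max() - y0) / cell_size)))
    grid = np.full((nrows, ncols), np.inf)
    col = np.clip(((bare_earth.x - x0) / cell_size).astype(int), 0, ncols - 1)
    row = np.clip(((bare_earth.y - y0) / cell_size).astype(int), 0, nrows - 1)
    np.minimum.at(grid, (row, col), bare_earth.z)
    empty = ~np.isfinite(grid)
    if empty.any():
        _, (ri, ci) = ndimage.distance_transform_edt(empty, return_indices=True)
        grid = grid[ri, ci]
    return TerrainModel(origin=(x0, y0), cell_size=cell_size, elevation=grid)


def normalize_heights(
    cloud: PointCloud,
    dtm: TerrainModel,
    ground_threshold: float = GROUND_THRESHOLD,
) -> HeightCloud:
    """Height-normalize a canopy-epoch cloud against the DTM.

    h = z − DTM(cell containing the point); the ground class is
    h < ground_threshold (a point exactly at the threshold is vegetation).
    """
    h = cloud.z - dtm.sample(cloud.x, cloud.y)
    return HeightCloud(cloud, h, h < ground_threshold, ground_threshold)
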