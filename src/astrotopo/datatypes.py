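"""Shared data containers: calibrated images, ROI polygons, point sets.

Coordinate conventions
----------------------
Point coordinates are in micrometres.  The +x axis is the mediolateral
direction (the tonotopic axis of the lateral superior olive) and +y is
dorsoventral (along isofrequency bands).  Raster images map pixel
``(row, col)`` to ``(x, y) = origin + (col, row) * pixel_size``, i.e. the
image row axis is the y axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


@dataclass
class FluorescenceImage:
    """A single-channel fluorescence image with spatial calibration.

    Parameters
    ----------
    intensities : ndarray of shape (rows, cols)
        Non-negative grey values (arbitrary units).
    pixel_size : float
        Pixel edge length in µm/pixel.
    origin : tuple of float
        µm coordinates ``(x0, y0)`` of the centre of pixel ``(0, 0)``.
    """

    intensities: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("image must be a 2-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("image intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("image intensities must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """µm coordinates of all pixel centres as ``(x, y)`` 2-D grids."""
        rows, cols = self.shape
        x = self.origin[0] + np.arange(cols) * self.pixel_size
        y = self.origin[1] + np.arange(rows) * self.pixel_size
        return np.meshgrid(x, y)

    def um_to_pixel(self, xy_um: np.ndarray) -> np.ndarray:
        """Convert µm coordinates ``(x, y)`` to fractional ``(row, col)``."""
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        col = (xy[:, 0] - self.origin[0]) / self.pixel_size
        row = (xy[:, 1] - self.origin[1]) / self.pixel_size
        return np.column_stack([row, col])


@dataclass
class RoiPolygon:
    """A polygonal region of interest with µm vertices.

    ``label`` names the anatomical nucleus (e.g. ``"LSO"``, ``"MNTB"``,
    ``"SPN"``) or ``"background"`` for negative-control regions.
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices must be finite")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"polygon {self.label!r} is self-intersecting or degenerate")
        if poly.area == 0:
            raise ValueError(f"polygon {self.label!r} has zero area")

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return float(self.shapely.area)


@dataclass
class NetworkPointSet:
    """A tracer-coupled network: the patched cell and its coupled cells.

    ``patched`` is the µm coordinate of the patch-clamped astrocyte from
    which the tracer spread; ``cells`` holds the coupled cells only (the
    patched cell is *not* repeated there).
    """

    patched: np.ndarray
    cells: np.ndarray
    peak_intensities: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.patched = np.asarray(self.patched, dtype=float).reshape(2)
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2 or self.cells.shape[1] != 2:
            raise ValueError("cells must be an (n, 2) array")
        if len(self.cells) < 1:
            raise ValueError("a network needs at least one coupled cell")
        if not (np.all(np.isfinite(self.patched)) and np.all(np.isfinite(self.cells))):
            raise ValueError("coordinates must be finite")

    @property
    def n_coupled(self) -> int:
        """Number of coupled cells (patched cell excluded)."""
        return len(self.cells)

    def all_points(self) -> np.ndarray:
        """Patched + coupled cells, patched first."""
        return np.vstack([self.patched[None, :], self.cells])

    def translated(self, offset) -> "NetworkPointSet":
        off = np.asarray(offset, dtype=float).reshape(2)
        return NetworkPointSet(self.patched + off, self.cells + off)

    def rotated(self, angle_deg: float) -> "NetworkPointSet":
        """Rotate all points counter-clockwise about the patched cell."""
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rel = (self.cells - self.patched) @ rot.T
        return NetworkPointSet(self.patched, self.patched + rel)
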