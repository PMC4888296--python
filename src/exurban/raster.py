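"""Georeferenced binary raster masks.

A :class:`BinaryLandscape` is the package's in-memory representation of a
single land-cover class (e.g. exurban development, forest) on a regular
square-pixel grid.  Rasters are stored as single-band uint8 TIFF files
(0 = background, 1 = foreground, 255 = nodata) with the affine georeference
kept in a sidecar ``<name>.json`` file next to the TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA_CODE = 255


@dataclass
class BinaryLandscape:
    """A binary land-cover mask on a square-pixel grid.

    Parameters
    ----------
    grid : ndarray of bool, shape (rows, cols)
        Foreground mask.
    pixel_size : float
        Side length of a pixel in metres (default 30, the Landsat TM pixel).
    origin : tuple of float
        ``(x_min, y_max)`` of the top-left raster corner in projected
        coordinates (metres).  Row ``r``, column ``c`` has its centre at
        ``(x_min + (c + 0.5) * pixel_size, y_max - (r + 0.5) * pixel_size)``.
    nodata : ndarray of bool or None
        Optional mask of cells with no valid observation.  Nodata cells are
        never foreground.
    """

    grid: np.ndarray
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.grid.dtype != bool:
            vals = np.unique(self.grid)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"grid must be binary (0/1); found values {vals[:10]}"
                )
            self.grid = self.grid.astype(bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nodata is not None:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.grid.shape:
                raise ValueError("nodata mask shape must match grid")
            # a cell is exactly one of foreground / background / nodata
            self.grid = self.grid & ~self.nodata

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster in map units."""
        rows, cols = self.grid.shape
        x0, y1 = self.origin
        return (x0, y1 - rows * self.pixel_size, x0 + cols * self.pixel_size, y1)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all cell centres."""
        rows, cols = self.grid.shape
        x0, y1 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = y1 - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    # ------------------------------------------------------------------ I/O
    def write(self, path: str | Path) -> None:
        """Write as single-band uint8 TIFF plus a georeference sidecar JSON."""
        path = Path(path)
        band = self.grid.astype(np.uint8)
        if self.nodata is not None:
            band = band.copy()
            band[self.nodata] = NODATA_CODE
        tifffile.imwrite(path, band)
        meta = {
            "pixel_size": self.pixel_size,
            "origin": list(self.origin),
            "nodata_value": NODATA_CODE,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def read(cls, path: str | Path) -> "BinaryLandscape":
        path = Path(path)
        band = np.asarray(tifffile.imread(path))
        sidecar = path.with_suffix(path.suffix + ".json")
        pixel_size, origin = 30.0, (0.0, 0.0)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = float(meta.get("pixel_size", 30.0))
            origin = tuple(meta.get("origin", (0.0, 0.0)))
        nodata = band == NODATA_CODE
        return cls(
            grid=(band == 1),
            pixel_size=pixel_size,
            origin=origin,
            nodata=nodata if nodata.any() else None,
        )
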