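"""Grid geometry and single-band raster I/O.

Rasters are plain row-major numpy arrays with the origin at the top-left
cell. Files are written as single-band TIFF via :mod:`tifffile`; grid
geometry (cell size, nodata sentinel) travels in the run manifest rather
than in embedded tags, and areas are always computed from ``cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError

__all__ = ["GridSpec", "write_raster", "read_raster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be at least 1.
    cell_size
        Side length of a square cell in metres.
    nodata_value
        Sentinel stored in exported rasters for undefined cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 250.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError(
                f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise InvalidParameterError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_m2 / 10_000.0

    @property
    def total_area_ha(self) -> float:
        return self.n_cells * self.cell_area_ha


def write_raster(path: str | Path, values: np.ndarray, *, nodata: float | None = None) -> Path:
    """Write a 2-D array as a single-band float32 TIFF."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise InvalidParameterError(f"expected a 2-D raster, got shape {arr.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = arr.astype(np.float32, copy=True)
    if nodata is not None:
        out = np.where(np.isfinite(out), out, np.float32(nodata))
    tifffile.imwrite(path, out)
    return path


def read_raster(path: str | Path) -> np.ndarray:
    """Read a single-band TIFF written by :func:`write_raster`."""
    return np.asarray(tifffile.imread(Path(path)))
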