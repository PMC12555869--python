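"""Minimal single-band raster container with ESRI ASCII-grid text I/O.

Rasters here live in a local planar coordinate system (km east/north of an
arbitrary origin, usually the radar).  Values are stored north-up: row 0 is
the northernmost row, matching the on-disk ASCII-grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values : 2-D float array, row 0 = northernmost row.
    x_min, y_min : coordinates of the grid's lower-left corner (km).
    cell_size : pixel edge length (km); pixels are square.
    nodata : value written for missing cells on export (NaN in memory).
    """

    values: np.ndarray
    x_min: float
    y_min: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def covers(self, x_min: float, y_min: float, x_max: float, y_max: float) -> bool:
        return (
            self.x_min <= x_min
            and self.y_min <= y_min
            and self.x_max >= x_max
            and self.y_max >= y_max
        )

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate vectors; y descends with row index."""
        x = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return x, y

    def sample(self, x, y):
        """Nearest-neighbour sample at coordinates (vectorised); NaN outside."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out[ok] = self.values[row[ok], col[ok]]
        return out if out.size > 1 else float(out[0])

    def disc_mean(self, x0: float, y0: float, radius: float) -> float:
        """Mean of pixels whose centres fall within a disc (footprint mean)."""
        x, y = self.pixel_centres()
        xx, yy = np.meshgrid(x, y)
        mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
        if not mask.any():
            # disc smaller than a pixel: fall back to the centre pixel
            v = self.sample(x0, y0)
            return float(v)
        vals = self.values[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    # -- ESRI ASCII grid I/O ------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x_min!r}\n"
            f"yllcorner {self.y_min!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value", -9999.0)
        vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            values=vals,
            x_min=meta["xllcorner"],
            y_min=meta["yllcorner"],
            cell_size=meta["cellsize"],
            nodata=nodata,
        )
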