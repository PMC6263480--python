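"""Gridded surface container (DSM / DTM / height map / soil mask).

Rasters are stored north-up with the origin at the upper-left cell corner;
row index increases southward (decreasing y), column index eastward
(increasing x). I/O uses the ESRI ASCII grid format, a plain-text standard
whose header carries the lower-left corner, cell size and nodata marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0

ROLES = ("dsm", "dtm", "height_map", "soil_mask", "generic")


class CongruenceError(ValueError):
    """Two rasters do not share shape, origin and cell size."""


@dataclass
class Raster:
    """A single-band grid of meters (or a 0/1 mask) with geo-placement.

    Parameters
    ----------
    values
        2D array, row 0 at the top (largest y).
    origin
        ``(x, y)`` of the upper-left corner of the upper-left cell.
    cell_size
        Ground sampling distance in meters (square cells).
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = NODATA
    role: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid extent."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column x centers and per-row y centers (y decreasing)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return xs, ys

    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values) | (self.values == self.nodata)

    def congruent(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_congruent(self, other: "Raster") -> None:
        if not self.congruent(other):
            raise CongruenceError(
                f"rasters not congruent: shape {self.shape} vs {other.shape}, "
                f"origin {self.origin} vs {other.origin}, "
                f"cell {self.cell_size} vs {other.cell_size}"
            )

    def like(self, values: np.ndarray, role: str | None = None) -> "Raster":
        """A new raster on the same grid with different values."""
        return Raster(
            values=np.asarray(values, dtype=float),
            origin=self.origin,
            cell_size=self.cell_size,
            nodata=self.nodata,
            role=self.role if role is None else role,
        )


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc) — plain text, lower-left referenced."""
    nrows, ncols = raster.shape
    _, ymin, _, _ = raster.bounds
    vals = np.where(raster.nodata_mask(), raster.nodata, raster.values)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.10g}\n"
        f"yllcorner {ymin:.10g}\n"
        f"cellsize {raster.cell_size:.10g}\n"
        f"NODATA_value {raster.nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path, role: str = "generic") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid header missing {req}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {values.shape} disagrees with header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Raster(
        values=values,
        origin=origin,
        cell_size=cell,
        nodata=header.get("nodata_value", NODATA),
        role=role,
    )
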