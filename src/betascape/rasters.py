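"""Single-band rasters and ESRI ASCII grid I/O.

Rasters are stored row-major with row 0 at the *top* (northernmost), the
standard raster convention.  ``origin`` is the lower-left corner in km of the
planar coordinate system; ``cell_size`` is in metres.  Habitat rasters hold
values in {0, 1, nodata}; climate rasters hold floats.

The on-disk format is the ESRI ASCII grid (``.asc``), a plain-text
interchange format readable by QGIS/GDAL.  The acquisition year is encoded in
the file name (``<name>__<year>.asc``) because the format has no metadata
slot for it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

NODATA = -9999


@dataclass
class Raster:
    """A single-band grid anchored in planar km coordinates."""

    grid: np.ndarray  # 2-D, row 0 = top
    cell_size: float  # metres
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) lower-left corner, km
    year: int | None = None
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise DataError("raster grid must be 2-D")
        if self.cell_size <= 0:
            raise DataError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def valid_mask(self) -> np.ndarray:
        g = self.grid
        mask = g != self.nodata
        if np.issubdtype(g.dtype, np.floating):
            mask &= ~np.isnan(g)
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) km coordinates of every cell center, same shape as grid."""
        nrows, ncols = self.grid.shape
        cs_km = self.cell_size / 1000.0
        x = self.origin[0] + (np.arange(ncols) + 0.5) * cs_km
        y = self.origin[1] + (nrows - np.arange(nrows) - 0.5) * cs_km
        return np.meshgrid(x, y)


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid; the year, if set, is appended to the stem."""
    path = Path(path)
    if raster.year is not None and "__" not in path.stem:
        path = path.with_name(f"{path.stem}__{raster.year}{path.suffix}")
    nrows, ncols = raster.grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]!r}\n"
        f"yllcorner {raster.origin[1]!r}\n"
        f"cellsize {raster.cell_size / 1000.0!r}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    g = raster.grid
    if np.issubdtype(g.dtype, np.floating):
        g = np.where(np.isnan(g), raster.nodata, g)
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in g)
    else:
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in g)
    path.write_text(header + body + "\n")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    lines = path.read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and re.match(r"^[A-Za-z_]+\s", lines[i]):
        key, val = lines[i].split(None, 1)
        hdr[key.lower()] = float(val)
        i += 1
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= hdr.keys():
        raise DataError(f"{path}: missing ASCII grid header fields")
    body = np.array(
        [[float(v) for v in line.split()] for line in lines[i:] if line.strip()]
    )
    if body.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise DataError(f"{path}: grid body does not match declared dimensions")
    if np.all(body == body.astype(np.int64)):
        body = body.astype(np.int64)
    year = None
    m = re.search(r"__(\d{4})$", path.stem)
    if m:
        year = int(m.group(1))
    return Raster(
        grid=body,
        cell_size=hdr["cellsize"] * 1000.0,
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        year=year,
        nodata=hdr.get("nodata_value", NODATA),
    )
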