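"""Minimal single-band raster container with plain-text (ESRI ASCII
grid) I/O and cell-center rasterization of polygons.

The landscape inputs (imperviousness, biotope classes) are regular
grids; 2 m cells are the working resolution. Values are stored as
float with NaN as nodata; class grids hold integer codes as floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    """North-up grid: ``data[0, 0]`` is the top-left (NW) cell.

    ``xll``/``yll`` are the coordinates of the lower-left *corner* of
    the grid; all cells are square with side ``cellsize`` metres.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shaped like data."""
        nrows, ncols = self.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    @property
    def mask(self) -> np.ndarray:
        """True where a value is present."""
        return np.isfinite(self.data)

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.xll, self.yll, self.cellsize, self.nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), NaN as the nodata value."""
    data = raster.data.copy()
    data[~np.isfinite(data)] = raster.nodata
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(raster.xll)!r}\n"
        f"yllcorner {float(raster.yll)!r}\n"
        f"cellsize {float(raster.cellsize)!r}\n"
        f"NODATA_value {float(raster.nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0][0].isalpha():
                break
            header[line[0].lower()] = float(line[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    nodata = header.get("nodata_value", -9999.0)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    data[data == nodata] = np.nan
    return Raster(data, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def rasterize_classes(
    polygons: list[tuple[int, "object"]], template: Raster
) -> Raster:
    """Burn (class_code, shapely polygon) pairs onto ``template``'s
    grid by cell-center containment; later polygons win ties. Cells
    covered by no polygon are NaN.
    """
    from shapely import contains_xy

    out = np.full(template.shape, np.nan)
    X, Y = template.cell_centers()
    for code, poly in polygons:
        inside = contains_xy(poly, X.ravel(), Y.ravel()).reshape(template.shape)
        out[inside] = float(code)
    return Raster(out, template.xll, template.yll, template.cellsize, template.nodata)
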