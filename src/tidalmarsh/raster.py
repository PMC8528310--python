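"""Minimal single-band raster I/O in the ESRI ASCII grid format.

Plain-text grids keep fixtures and outputs portable; only the subset of
the format the package needs (cellsize, corner registration, nodata) is
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class AsciiGrid:
    """A single-band grid: ``data`` with NaN at nodata cells, plus the
    georeferencing header fields."""

    data: np.ndarray
    cellsize: float = 5.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.data)


def write_ascii_grid(path: str | Path, grid: AsciiGrid) -> None:
    nrows, ncols = grid.data.shape
    out = np.where(np.isfinite(grid.data), grid.data, grid.nodata_value)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.xllcorner}\n"
        f"yllcorner {grid.yllcorner}\n"
        f"cellsize {grid.cellsize}\n"
        f"NODATA_value {grid.nodata_value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    data = data.reshape(expected)
    return AsciiGrid(
        data=data,
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata_value=nodata,
    )
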