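"""Categorical and continuous raster containers with lightweight text/TIFF I/O.

Rasters are plain numpy grids with a cell size and an origin; georeferencing
beyond an axis-aligned affine (origin + square cells) is out of scope. The
ESRI ASCII grid format is supported because it is a portable plain-text
interchange format; TIFF (via tifffile) covers the binary route.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_NODATA = 255


@dataclass
class LandUseRaster:
    """Integer-coded categorical grid for one zone and epoch.

    Parameters
    ----------
    data : 2-D integer array of class codes.
    cell_size : edge length of a (square) cell, in map units (metres).
    nodata : code marking cells outside the analysis region.
    origin : (x, y) map coordinates of the lower-left corner.
    """

    data: np.ndarray
    cell_size: float = 1.0
    nodata: int = DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("land-use raster requires integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def class_counts(self) -> dict[int, int]:
        """Cell counts per class code, nodata excluded."""
        vals, counts = np.unique(self.data[self.valid_mask], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def class_proportions(self) -> dict[int, float]:
        n = self.n_valid
        if n == 0:
            raise ValueError("raster contains no valid (non-nodata) cells")
        return {k: c / n for k, c in self.class_counts().items()}


def write_ascii_grid(raster: LandUseRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), a plain-text raster interchange format."""
    rows, cols = raster.shape
    x0, y0 = raster.origin
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids store the top row first
        for row in raster.data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> LandUseRaster:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                hdr[key] = float(val)
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    nodata = int(hdr.get("nodata_value", DEFAULT_NODATA))
    return LandUseRaster(
        data=data,
        cell_size=hdr.get("cellsize", 1.0),
        nodata=nodata,
        origin=(hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0)),
    )


def write_tiff(raster: LandUseRaster, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(
        str(path),
        raster.data.astype(np.uint8 if raster.data.max(initial=0) < 256 else np.int32),
        metadata={
            "cell_size": raster.cell_size,
            "nodata": raster.nodata,
            "origin": list(raster.origin),
        },
    )


def read_tiff(path: str | Path, cell_size: float = 1.0, nodata: int = DEFAULT_NODATA) -> LandUseRaster:
    import tifffile

    data = np.asarray(tifffile.imread(str(path))).astype(np.int64)
    return LandUseRaster(data=data, cell_size=cell_size, nodata=nodata)
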