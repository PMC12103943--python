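"""Non-landscape PSR indicators: ecosystem service value, land-use
intensity, NDVI and zonal aggregation.

ESV uses the equivalent-coefficient method: per-class value coefficients
(currency per unit area) times class areas. The coefficient table is a
required configuration input; the published benchmark tables are not
bundled, and the default table used in tests is synthetic.

LUI is the area-weighted mean of ordinal intensity grades per land-use
class, bounded by the smallest and largest grade in the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.prepared import prep

from .raster import LandUseRaster

__all__ = [
    "EsvCoefficientTable",
    "LuiGradeTable",
    "DEFAULT_LUI_GRADES",
    "esv",
    "lui",
    "ndvi",
    "zonal_mean",
]

# canonical class codes used throughout the package
CONSTRUCTION, ARABLE, GRASSLAND, FOREST, WATER, UNUSED = 1, 2, 3, 4, 5, 6

#: intensity grade per land-use class: construction 4, arable 3,
#: grassland 2.5, forest 2, water 2, unused 1
DEFAULT_LUI_GRADES: dict[int, float] = {
    CONSTRUCTION: 4.0,
    ARABLE: 3.0,
    GRASSLAND: 2.5,
    FOREST: 2.0,
    WATER: 2.0,
    UNUSED: 1.0,
}


def _read_class_table(path: str | Path, value_col: str) -> dict[int, float]:
    df = pd.read_csv(path)
    return {int(r["class_code"]): float(r[value_col]) for _, r in df.iterrows()}


@dataclass
class EsvCoefficientTable:
    """Per-class ecosystem-service value coefficients (currency / area unit)."""

    coefficients: dict[int, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("ESV coefficients must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EsvCoefficientTable":
        return cls(_read_class_table(path, "value"))


@dataclass
class LuiGradeTable:
    """Per-class land-use intensity grades."""

    grades: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LUI_GRADES))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LuiGradeTable":
        return cls(_read_class_table(path, "value"))


def esv(raster: LandUseRaster, table: EsvCoefficientTable) -> float:
    """Total ecosystem service value: Σ_classes area_i × V_i.

    Areas are cell counts × cell area, so the result carries the
    coefficient's currency unit.
    """
    counts = raster.class_counts()
    missing = sorted(set(counts) - set(table.coefficients))
    if missing:
        raise KeyError(f"no ESV coefficient for class code(s) {missing}")
    return float(
        sum(counts[c] * raster.cell_area * table.coefficients[c] for c in counts)
    )


def lui(raster: LandUseRaster, table: LuiGradeTable | None = None) -> float:
    """Land-use intensity: Σ A_i S_i / S_c, the grade-weighted mean over the zone.

    A_i is the intensity grade of class i, S_i its area and S_c the total
    area; the result lies in [min grade, max grade] ([1, 4] by default).
    """
    table = table or LuiGradeTable()
    counts = raster.class_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("LUI undefined on a raster with zero valid area")
    missing = sorted(set(counts) - set(table.grades))
    if missing:
        raise KeyError(f"no intensity grade for class code(s) {missing}")
    return float(sum(table.grades[c] * n for c, n in counts.items()) / total)


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index, (NIR − R) / (NIR + R).

    Zero-sum cells (no signal) map to 0.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, 0.0)
    return out


def zonal_mean(
    values: np.ndarray,
    zones: dict[object, Polygon],
    cell_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: float | None = None,
) -> pd.Series:
    """Mean of cell values whose centres fall inside each zone polygon.

    ``values`` follows raster orientation: row 0 is the top of the map.
    Zones covering no valid cell centre get NaN (flagged, never silent 0).
    """
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * cell_size
    ys = y0 + (rows - np.arange(rows) - 0.5) * cell_size  # row 0 at the top
    xx, yy = np.meshgrid(xs, ys)
    valid = np.isfinite(values)
    if nodata is not None:
        valid &= values != nodata

    out = {}
    for zid, poly in zones.items():
        prepared = prep(poly)
        # bounding-box prefilter keeps the point-in-polygon loop small
        minx, miny, maxx, maxy = poly.bounds
        box = (xx >= minx) & (xx <= maxx) & (yy >= miny) & (yy <= maxy) & valid
        idx = np.argwhere(box)
        picked = []
        from shapely.geometry import Point

        for r, c in idx:
            if prepared.intersects(Point(xx[r, c], yy[r, c])):
                picked.append(values[r, c])
        out[zid] = float(np.mean(picked)) if picked else np.nan
    return pd.Series(out, name="zonal_mean")
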