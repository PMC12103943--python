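"""Landscape composition and configuration metrics on categorical rasters.

Implements the five class-mosaic indices used as ecosystem-state and
-response indicators: Shannon diversity (SHDI) and evenness (SHEI), patch
cohesion (COHESION), contagion (CONTAG) and mean patch fractal dimension
(FRAC_MN), following the standard Fragstats definitions.

Conventions
-----------
* Patches are connected components of same-class cells; connectivity is 8
  (queen) by default, configurable to 4 (rook).
* Perimeter is measured in cell-edge units: the number of cell sides
  adjacent to a different class, a nodata cell, or the raster boundary.
  Multiply by ``cell_size`` for metric perimeters.
* Adjacency counts ``g_ik`` for contagion use the double-count convention
  (each internal cell side contributes once per direction).
* nodata cells are excluded from cell totals, proportions and adjacency
  counts, but edges against nodata do contribute patch perimeter.
* Single-class landscapes: SHEI is defined as 0, CONTAG raises; single-cell
  patches take fractal dimension 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

from .raster import LandUseRaster

__all__ = [
    "Patch",
    "PatchSet",
    "LandscapeMetrics",
    "delineate_patches",
    "shdi",
    "shei",
    "cohesion",
    "contag",
    "frac_mn",
    "compute_all_metrics",
]


@dataclass(frozen=True)
class Patch:
    class_code: int
    area: int  # cells
    perimeter: int  # cell-edge units


@dataclass
class PatchSet:
    patches: list[Patch]
    connectivity: int
    n_cells: int  # total valid cells in the landscape

    def __post_init__(self) -> None:
        total = sum(p.area for p in self.patches)
        if total != self.n_cells:
            raise ValueError(
                f"patch areas ({total}) do not partition the landscape ({self.n_cells} cells)"
            )

    def __len__(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class LandscapeMetrics:
    shdi: float
    shei: float
    cohesion: float
    contag: float | None
    frac_mn: float
    n_classes: int
    proportions: dict[int, float]


def _check_connectivity(connectivity: int) -> int:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    # skimage uses 1 (orthogonal) / 2 (orthogonal+diagonal)
    return 1 if connectivity == 4 else 2


def delineate_patches(raster: LandUseRaster, connectivity: int = 8) -> PatchSet:
    """Split a categorical raster into same-class connected components.

    Perimeter of each patch counts cell sides facing another class, nodata
    or the raster boundary. Orthogonally adjacent same-class cells always
    belong to the same patch (under either connectivity), so per-class edge
    counting yields exact per-patch perimeters.
    """
    skim_conn = _check_connectivity(connectivity)
    valid = raster.valid_mask
    if not valid.any():
        raise ValueError("cannot delineate patches on an all-nodata raster")

    data = raster.data
    patches: list[Patch] = []
    for code in sorted(raster.class_counts()):
        mask = data == code
        labels, n_lab = _cc_label(mask, connectivity=skim_conn, return_num=True)
        # edge faces a different class / nodata / boundary
        edge = np.zeros(mask.shape, dtype=np.int64)
        padded = np.pad(mask, 1, constant_values=False)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            neigh = np.roll(padded, shift, axis=axis)[1:-1, 1:-1]
            edge += mask & ~neigh
        for lab in range(1, n_lab + 1):
            member = labels == lab
            patches.append(
                Patch(
                    class_code=code,
                    area=int(member.sum()),
                    perimeter=int(edge[member].sum()),
                )
            )
    return PatchSet(patches=patches, connectivity=connectivity, n_cells=int(valid.sum()))


def shdi(proportions) -> float:
    """Shannon diversity of class proportions, in nats. 0·ln 0 := 0."""
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict) else proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1, got {p.sum():.6f}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shei(proportions) -> float:
    """Shannon evenness: SHDI / ln m over the m classes present; 0 if m == 1."""
    p = np.asarray(list(proportions.values()) if isinstance(proportions, dict) else proportions, dtype=float)
    m = int((p > 0).sum())
    if m <= 1:
        return 0.0
    return shdi(p) / np.log(m)


def cohesion(patchset: PatchSet) -> float:
    """Patch cohesion index (percent): physical connectedness of patches.

    100 * [1 - Σp_ij / Σ(p_ij sqrt(a_ij))] / [1 - 1/sqrt(N)] with perimeters
    and areas in cell units and N the number of valid cells.
    """
    n = patchset.n_cells
    if n <= 1:
        raise ValueError("cohesion undefined for a single-cell landscape")
    perim = np.array([p.perimeter for p in patchset.patches], dtype=float)
    area = np.array([p.area for p in patchset.patches], dtype=float)
    num = perim.sum()
    den = (perim * np.sqrt(area)).sum()
    return float(100.0 * (1.0 - num / den) / (1.0 - 1.0 / np.sqrt(n)))


def _adjacency_counts(raster: LandUseRaster) -> tuple[np.ndarray, np.ndarray]:
    """Class adjacency matrix g_ik under the double-count convention.

    Only orthogonal cell sides between two valid cells are counted; each
    side contributes to both g_ik and g_ki (so like-adjacencies land on the
    diagonal twice).
    """
    data = raster.data
    valid = raster.valid_mask
    codes = np.array(sorted(raster.class_counts()))
    index = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m), dtype=np.int64)
    for sl_a, sl_b in (
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),  # vertical pairs
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),  # horizontal pairs
    ):
        a, b = data[sl_a], data[sl_b]
        ok = valid[sl_a] & valid[sl_b]
        ai = np.vectorize(index.get, otypes=[np.int64])(a[ok]) if ok.any() else np.array([], dtype=np.int64)
        bi = np.vectorize(index.get, otypes=[np.int64])(b[ok]) if ok.any() else np.array([], dtype=np.int64)
        np.add.at(g, (ai, bi), 1)
        np.add.at(g, (bi, ai), 1)
    return codes, g


def contag(raster: LandUseRaster) -> float:
    """Contagion index (percent): aggregation of class adjacencies.

    100 * [1 + ΣΣ q_ik ln q_ik / (2 ln m)] with q_ik = P_i * g_ik / Σ_k g_ik.
    Requires at least two classes (Fragstats convention).
    """
    props = raster.class_proportions()
    codes = np.array(sorted(props))
    m = len(codes)
    if m < 2:
        raise ValueError("contagion is undefined for a single-class landscape")
    _, g = _adjacency_counts(raster)
    p_i = np.array([props[c] for c in codes])
    row_sums = g.sum(axis=1, keepdims=True).astype(float)
    # a class may have no counted adjacencies (e.g. isolated by nodata)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = p_i[:, None] * np.where(row_sums > 0, g / row_sums, 0.0)
    nz = q[q > 0]
    ent = float((nz * np.log(nz)).sum())
    return float(100.0 * (1.0 + ent / (2.0 * np.log(m))))


def frac_mn(patchset: PatchSet) -> float:
    """Mean patch fractal dimension: 2 ln(0.25 p) / ln(a) averaged over patches.

    Single-cell patches (ln a = 0) take the value 1 by convention.
    """
    if len(patchset) == 0:
        raise ValueError("empty patch set")
    vals = []
    for p in patchset.patches:
        if p.area <= 1:
            vals.append(1.0)
        else:
            vals.append(2.0 * np.log(0.25 * p.perimeter) / np.log(p.area))
    return float(np.mean(vals))


def compute_all_metrics(raster: LandUseRaster, connectivity: int = 8) -> LandscapeMetrics:
    """All five indices for one landscape; CONTAG is None when only one class is present."""
    props = raster.class_proportions()
    ps = delineate_patches(raster, connectivity=connectivity)
    m = len(props)
    return LandscapeMetrics(
        shdi=shdi(props),
        shei=shei(props),
        cohesion=cohesion(ps),
        contag=contag(raster) if m >= 2 else None,
        frac_mn=frac_mn(ps),
        n_classes=m,
        proportions=props,
    )
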