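"""Spatial autocorrelation of zone-level values: global and local Moran's I.

Weights come from queen contiguity of the zone polygons (any shared
boundary point), row-standardized. Inference combines the analytic
randomization z-score with a seeded permutation test (pseudo p-value
(#extreme + 1)/(n_perm + 1)); local statistics use conditional
permutations that hold the focal value fixed.

LISA cluster labels follow the Moran-scatterplot quadrant of
(z_i, spatial lag of z): H-H, L-L, H-L, L-H, assigned only where the
local pseudo p falls below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LisaResult",
    "queen_weights",
    "rook_weights",
    "lattice_weights",
    "global_moran",
    "local_moran",
]


@dataclass
class SpatialWeights:
    """Row-standardized n×n contiguity weights.

    ``binary`` keeps the symmetric 0/1 adjacency; ``matrix`` is the
    row-standardized form actually used in the statistics. Islands (zones
    with no neighbours) keep an all-zero row.
    """

    binary: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        B = np.asarray(self.binary, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("weights must be square")
        if np.diag(B).any():
            raise ValueError("self-neighbour (nonzero diagonal) not allowed")
        if not np.allclose(B, B.T):
            raise ValueError("binary contiguity must be symmetric")
        self.binary = B
        if not self.ids:
            self.ids = list(range(B.shape[0]))
        rs = B.sum(axis=1)
        self.islands = [self.ids[i] for i in np.flatnonzero(rs == 0)]
        if self.islands:
            warnings.warn(f"island zones with no neighbours: {self.islands}", stacklevel=2)
        self.matrix = np.divide(B, rs[:, None], out=np.zeros_like(B), where=rs[:, None] > 0)

    @property
    def n(self) -> int:
        return self.binary.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.binary[i] > 0)


def _contiguity(zones: dict[object, Polygon], queen: bool) -> SpatialWeights:
    ids = list(zones)
    if len(ids) < 2:
        raise ValueError("need at least 2 zones for contiguity weights")
    polys = [zones[i] for i in ids]
    n = len(polys)
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = polys[i].boundary.intersection(polys[j].boundary)
            if inter.is_empty:
                continue
            if queen:
                B[i, j] = B[j, i] = 1.0  # any shared boundary point
            elif inter.length > 0:  # rook: shared edge, not just a corner
                B[i, j] = B[j, i] = 1.0
    return SpatialWeights(binary=B, ids=ids)


def queen_weights(zones: dict[object, Polygon]) -> SpatialWeights:
    """Queen contiguity: zones sharing any boundary point are neighbours."""
    return _contiguity(zones, queen=True)


def rook_weights(zones: dict[object, Polygon]) -> SpatialWeights:
    """Rook contiguity: zones sharing a boundary segment of positive length."""
    return _contiguity(zones, queen=False)


def lattice_weights(rows: int, cols: int, rook: bool = True) -> SpatialWeights:
    """Contiguity weights of a regular rows×cols lattice (row-major ids)."""
    n = rows * cols
    B = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if not rook:
                steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    B[i, rr * cols + cc] = 1.0
    return SpatialWeights(binary=B)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    z: float
    p_perm: float
    p_norm: float
    n_perm: int
    seed: int


@dataclass
class LisaResult:
    local_I: np.ndarray
    z: np.ndarray
    p_perm: np.ndarray
    labels: list[str]
    alpha: float
    n_perm: int
    seed: int

    def to_frame(self, ids=None) -> pd.DataFrame:
        return pd.DataFrame(
            {"local_I": self.local_I, "z": self.z, "p": self.p_perm, "cluster": self.labels},
            index=ids,
        )


def _moran_stat(x: np.ndarray, W: np.ndarray) -> float:
    z = x - x.mean()
    s0 = W.sum()
    return float(len(x) / s0 * (z @ W @ z) / (z @ z))


def global_moran(
    values, weights: SpatialWeights, n_perm: int = 999, seed: int = 0
) -> MoranResult:
    """Global Moran's I with randomization z-score and permutation pseudo p.

    I = (n / S0) ΣΣ W_ij (x_i − x̄)(x_j − x̄) / Σ (x_i − x̄)², with the
    z-score from the randomization (sampling-without-replacement) variance
    and a one-sided pseudo p from value permutations.
    """
    x = np.asarray(values, dtype=float)
    W = weights.matrix
    n = len(x)
    if n != weights.n:
        raise ValueError(f"{n} values but {weights.n} zones")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values (zero variance)")

    I = _moran_stat(x, W)
    EI = -1.0 / (n - 1)

    # randomization variance (Cliff & Ord)
    z = x - x.mean()
    s0 = W.sum()
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum()
    m2 = (z**2).sum() / n
    m4 = (z**4).sum() / n
    b2 = m4 / m2**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var_I = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - EI**2
    zscore = (I - EI) / np.sqrt(var_I)

    from scipy.stats import norm

    p_norm = float(2 * norm.sf(abs(zscore)))

    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for k in range(n_perm):
        sims[k] = _moran_stat(rng.permutation(x), W)
    if I >= EI:
        extreme = int((sims >= I).sum())
    else:
        extreme = int((sims <= I).sum())
    p_perm = (extreme + 1) / (n_perm + 1)

    return MoranResult(
        I=I, expected=EI, z=float(zscore), p_perm=float(p_perm), p_norm=p_norm,
        n_perm=n_perm, seed=seed,
    )


def local_moran(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> LisaResult:
    """Anselin's local Moran I_i with conditional-permutation inference.

    I_i = (z_i / m2) Σ_j W_ij z_j with m2 = Σ z² / n, so that
    Σ_i I_i = S0 · I_global (n · I under row standardization). The
    conditional permutation shuffles all other values across the
    neighbours of i while holding x_i fixed.
    """
    x = np.asarray(values, dtype=float)
    W = weights.matrix
    n = len(x)
    if n != weights.n:
        raise ValueError(f"{n} values but {weights.n} zones")
    if np.ptp(x) == 0:
        raise ValueError("local Moran undefined for constant values")

    z = x - x.mean()
    m2 = (z**2).sum() / n
    lag = W @ z
    Ii = z * lag / m2

    rng = np.random.default_rng(seed)
    p_perm = np.ones(n)
    z_sim = np.zeros(n)
    others_all = np.arange(n)
    for i in range(n):
        nbrs = weights.neighbors(i)
        k = len(nbrs)
        if k == 0:
            p_perm[i] = np.nan
            continue
        others = z[others_all != i]
        sims = np.empty(n_perm)
        wrow = W[i, nbrs]
        for s in range(n_perm):
            draw = rng.choice(others, size=k, replace=False)
            sims[s] = z[i] * (wrow @ draw) / m2
        if Ii[i] >= sims.mean():
            extreme = int((sims >= Ii[i]).sum())
        else:
            extreme = int((sims <= Ii[i]).sum())
        p_perm[i] = (extreme + 1) / (n_perm + 1)
        sd = sims.std(ddof=1)
        z_sim[i] = (Ii[i] - sims.mean()) / sd if sd > 0 else np.nan

    labels = []
    for i in range(n):
        if not np.isfinite(p_perm[i]) or p_perm[i] >= alpha:
            labels.append("not significant")
        elif z[i] >= 0 and lag[i] >= 0:
            labels.append("H-H")
        elif z[i] < 0 and lag[i] < 0:
            labels.append("L-L")
        elif z[i] >= 0:
            labels.append("H-L")
        else:
            labels.append("L-H")

    return LisaResult(
        local_I=Ii, z=z_sim, p_perm=p_perm, labels=labels,
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
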