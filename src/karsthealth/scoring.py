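"""Entropy-weighted composite Ecosystem Health Index (EHI).

The eight PSR indicators (POP; NDVI, SHDI, SHEI, COHESION; ESV, CONTAG,
FRAC_MN) are min-max normalized over the pooled zone-year sample, weighted
by the entropy weight method (indicators with greater cross-sample
dispersion — lower information entropy — receive larger weights), and
summed into an EHI in [0, 1] per zone-year.

Normalization
-------------
Positive indicators: (x − min) / (max − min).
Negative indicators (higher is worse, here POP): (max − x) / (max − min),
the standard orientation-reversing form, so every normalized value lands
in [0, 1] as required by the entropy step's logarithms.

Entropy weights
---------------
f_ij = Y_ij / Σ_j Y_ij,  E_i = −(1/ln n) Σ_j f_ij ln f_ij  (0 ln 0 := 0),
d_i = 1 − E_i,  w_i = d_i / Σ_i d_i.  A constant (all-zero after
normalization) indicator carries no information and gets weight 0.

Grades
------
EHI grades are I [0, 0.5), II [0.5, 0.55), III [0.55, 0.6), IV [0.6, 1]
(half-open, boundary assigned upward). ΔEHI (last − first epoch) change
levels: I [0.06, 0.08), II [0.08, 0.10), III [0.10, 0.13]; values outside
[0.06, 0.13] are labelled out-of-range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "INDICATOR_ORIENTATIONS",
    "PSR_LAYERS",
    "EntropyWeightScorer",
    "normalize_panel",
    "entropy_weights",
    "compute_ehi",
    "classify_ehi",
    "classify_delta",
    "aggregate_criterion_weights",
]

#: orientation per indicator: +1 higher-is-healthier, -1 higher-is-worse
INDICATOR_ORIENTATIONS: dict[str, int] = {
    "POP": -1,
    "NDVI": 1,
    "SHDI": 1,
    "SHEI": 1,
    "COHESION": 1,
    "ESV": 1,
    "CONTAG": 1,
    "FRAC_MN": 1,
}

#: pressure-state-response criterion layers
PSR_LAYERS: dict[str, tuple[str, ...]] = {
    "pressure": ("POP",),
    "state": ("NDVI", "SHDI", "SHEI", "COHESION"),
    "response": ("ESV", "CONTAG", "FRAC_MN"),
}

GRADE_EDGES = (0.5, 0.55, 0.6)
GRADE_LABELS = ("I", "II", "III", "IV")
DELTA_BANDS = ((0.06, 0.08, "I"), (0.08, 0.10, "II"), (0.10, 0.13, "III"))


def normalize_panel(X: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Min-max normalize columns to [0, 1], reversing negative indicators.

    Extrema are taken over the pooled sample (all rows), so scores stay
    comparable across zones and years. A constant column normalizes to all
    zeros with a warning; its entropy weight is then 0 downstream.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(
            f"constant indicator column(s) at index {np.flatnonzero(const).tolist()}; "
            "normalized to zero (weight will be 0)",
            stacklevel=2,
        )
    safe_span = np.where(const, 1.0, span)
    Y = np.where(orientations > 0, (X - lo) / safe_span, (hi - X) / safe_span)
    Y[:, const] = 0.0
    return Y


def entropy_weights(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entropy weights of a normalized (non-negative) matrix.

    Returns (weights w, entropies E, difference coefficients d). Columns
    that are identically zero get E = 1, d = 0, w = 0.
    """
    Y = np.asarray(Y, dtype=float)
    n, _ = Y.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 observations (k = 1/ln n)")
    if (Y < 0).any():
        raise ValueError("normalized matrix must be non-negative")
    col_sums = Y.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(col_sums > 0, Y / np.where(col_sums > 0, col_sums, 1.0), 0.0)
        flogf = np.where(f > 0, f * np.log(f), 0.0)
    k = 1.0 / np.log(n)
    E = np.where(col_sums > 0, -k * flogf.sum(axis=0), 1.0)
    d = 1.0 - E
    d = np.clip(d, 0.0, None)  # guard tiny negative from rounding
    if d.sum() == 0:
        raise ValueError("all indicators are constant; entropy weights undefined")
    w = d / d.sum()
    return w, E, d


def compute_ehi(Y: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Composite index per observation: Σ_i w_i Y_ij, in [0, 1]."""
    Y = np.asarray(Y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if Y.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: {Y.shape[1]} indicators vs {weights.shape[0]} weights"
        )
    return Y @ weights


def classify_ehi(value: float) -> str:
    """Four-grade classification of an EHI value in [0, 1]."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"EHI must lie in [0, 1], got {value}")
    for edge, lab in zip(GRADE_EDGES, GRADE_LABELS[:-1]):
        if value < edge:
            return lab
    return GRADE_LABELS[-1]


def classify_delta(delta: float) -> str:
    """Three-level classification of an EHI change; outside the band -> 'out-of-range'."""
    for lo, hi, lab in DELTA_BANDS:
        if lo <= delta < hi:
            return lab
    if delta == DELTA_BANDS[-1][1]:  # closed upper end of the band
        return DELTA_BANDS[-1][2]
    return "out-of-range"


def aggregate_criterion_weights(
    weights: pd.Series, layers: dict[str, tuple[str, ...]] | None = None
) -> pd.Series:
    """Criterion-layer weights as sums of member indicator weights."""
    layers = layers or PSR_LAYERS
    return pd.Series(
        {layer: float(weights[list(members)].sum()) for layer, members in layers.items()},
        name="criterion_weight",
    )


class EntropyWeightScorer(BaseEstimator, TransformerMixin):
    """Entropy-weight composite scorer, sklearn transformer style.

    ``fit`` learns pooled min/max per indicator and the entropy weights;
    ``transform`` maps raw indicator rows to composite scores (column
    vector). Out-of-training-range values are clipped to [0, 1] after
    normalization so transformed scores stay inside the index's domain.

    Parameters
    ----------
    orientations : sequence of +1/-1 per column, or None to look columns up
        by name in ``INDICATOR_ORIENTATIONS`` (requires DataFrame input).
    """

    def __init__(self, orientations=None):
        self.orientations = orientations

    def _resolve_orientations(self, X) -> np.ndarray:
        if self.orientations is not None:
            ori = np.asarray(self.orientations, dtype=int)
        elif isinstance(X, pd.DataFrame):
            try:
                ori = np.array([INDICATOR_ORIENTATIONS[c] for c in X.columns], dtype=int)
            except KeyError as exc:
                raise ValueError(
                    f"unknown indicator column {exc}; pass orientations explicitly"
                ) from None
        else:
            raise ValueError("orientations required for array input")
        if not np.isin(ori, (-1, 1)).all():
            raise ValueError("orientations must be +1 or -1")
        return ori

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        ori = self._resolve_orientations(X)
        X = check_array(X, ensure_min_samples=2)
        if ori.shape[0] != X.shape[1]:
            raise ValueError("orientations length does not match number of columns")
        self.orientations_ = ori
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        Y = normalize_panel(X, ori)
        self.normalized_ = Y
        self.weights_, self.entropies_, self.diff_coefs_ = entropy_weights(Y)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X)
        span = self.data_max_ - self.data_min_
        safe = np.where(span == 0, 1.0, span)
        Y = np.where(
            self.orientations_ > 0,
            (X - self.data_min_) / safe,
            (self.data_max_ - X) / safe,
        )
        Y[:, span == 0] = 0.0
        Y = np.clip(Y, 0.0, 1.0)
        return (Y @ self.weights_)[:, None]

    def score_panel(self, panel: pd.DataFrame) -> pd.Series:
        """Convenience: EHI per row of an indicator DataFrame (training data)."""
        check_is_fitted(self, "weights_")
        return pd.Series(
            compute_ehi(self.normalized_, self.weights_), index=panel.index, name="EHI"
        )

    @property
    def weight_series_(self) -> pd.Series:
        check_is_fitted(self, "weights_")
        names = getattr(self, "feature_names_in_", None)
        idx = names if names is not None else np.arange(self.n_features_in_)
        return pd.Series(self.weights_, index=idx, name="weight")
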