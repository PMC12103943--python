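"""Geographically and temporally weighted regression (GTWR) and the
collinearity screen that precedes it.

The model is Y_i = β0(u_i, v_i, t_i) + Σ_l β_l(u_i, v_i, t_i) X_il + δ_i:
an ordinary linear regression whose coefficients vary smoothly over space
and time. At each observation a weighted least-squares fit is solved with
kernel weights decaying in the combined space-time distance

    d²_ij = (u_i − u_j)² + (v_i − v_j)² + τ (t_i − t_j)²,
    w_ij = exp(−d²_ij / h²)          (Gaussian kernel),

where h is the spatial bandwidth and τ the space-time scaling ratio.
τ = 0 collapses to plain GWR; h → ∞ collapses to global OLS. Bandwidth
(and optionally τ) are selected by minimizing the corrected Akaike
criterion AICc via golden-section search nested in a τ grid.

Coordinates must be planar (project before fitting); time is numeric
(e.g. years since the first epoch), with τ carrying the unit conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "VIFScreener",
    "GTWR",
    "st_weights",
    "vif_scores",
    "vif_screen",
    "select_bandwidth",
    "classify_coefficients",
]


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def vif_scores(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 − R²) of the auxiliary
    regression of that column (with intercept) on all the others.
    Perfectly collinear columns get inf."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 candidate drivers")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(
    panel: pd.DataFrame, drivers: list[str] | None = None, threshold: float = 7.5
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF driver while any VIF > threshold.

    Returns (retained driver names, report of per-round VIFs with the
    removed driver flagged). Perfectly collinear drivers (infinite VIF)
    are removed first.
    """
    cols = list(drivers) if drivers is not None else list(panel.columns)
    report_rows = []
    round_no = 0
    while len(cols) >= 2:
        v = vif_scores(panel[cols].to_numpy())
        worst = int(np.argmax(v))
        removed = v[worst] > threshold
        for c, vi in zip(cols, v):
            report_rows.append(
                {"round": round_no, "driver": c, "vif": vi,
                 "removed": removed and c == cols[worst]}
            )
        if not removed:
            break
        cols = [c for k, c in enumerate(cols) if k != worst]
        round_no += 1
    return cols, pd.DataFrame(report_rows)


class VIFScreener(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping the iterative VIF screen.

    Fitted attributes: ``support_`` boolean mask of retained columns,
    ``retained_`` names (DataFrame input), ``report_`` per-round VIF table.
    """

    def __init__(self, threshold: float = 7.5):
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            df = X
        else:
            X = check_array(X)
            names = [f"x{j}" for j in range(X.shape[1])]
            df = pd.DataFrame(X, columns=names)
        retained, report = vif_screen(df, threshold=self.threshold)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.retained_ = retained
        self.report_ = report
        self.support_ = np.array([c in retained for c in names])
        self.n_features_in_ = len(names)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.retained_]
        X = check_array(X)
        return X[:, self.support_]


# ---------------------------------------------------------------------------
# space-time kernel weights
# ---------------------------------------------------------------------------

def st_weights(
    target: np.ndarray,
    coords: np.ndarray,
    h: float,
    tau: float,
    kernel: str = "gaussian",
) -> np.ndarray:
    """Kernel weights of every observation relative to one target point.

    ``target`` is (u, v, t); ``coords`` is (n, 3). The squared space-time
    distance is Δu² + Δv² + τ·Δt²; the Gaussian kernel exp(−d²/h²) (or
    bisquare (1 − d²/h²)² for d < h) maps it to a weight, with the target
    itself always at weight 1.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    if tau < 0:
        raise ValueError("space-time ratio tau must be non-negative")
    target = np.asarray(target, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if not (np.isfinite(target).all() and np.isfinite(coords).all()):
        raise ValueError("non-finite coordinates")
    d2 = (
        (coords[:, 0] - target[0]) ** 2
        + (coords[:, 1] - target[1]) ** 2
        + tau * (coords[:, 2] - target[2]) ** 2
    )
    if kernel == "gaussian":
        return np.exp(-d2 / h**2)
    if kernel == "bisquare":
        r = d2 / h**2
        return np.where(r < 1.0, (1.0 - r) ** 2, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class GTWR(BaseEstimator, RegressorMixin):
    """Geographically and temporally weighted regression.

    Parameters
    ----------
    bandwidth : spatial kernel bandwidth h (map units). None selects it by
        AICc at fit time.
    tau : space-time distance ratio; 0 ignores time (GWR).
    kernel : 'gaussian' (default) or 'bisquare'.
    tau_grid : candidate τ values when both bandwidth and τ are selected.
    fit_intercept : include a local intercept β0(u, v, t).

    Fitted attributes
    -----------------
    coef_ : (n_obs, n_drivers) local slopes at each training observation.
    intercept_ : (n_obs,) local intercepts.
    residuals_, fitted_, hat_diag_, hat_trace_, aicc_, r2_, bandwidth_, tau_.
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        tau: float | None = 1.0,
        kernel: str = "gaussian",
        tau_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
        fit_intercept: bool = True,
    ):
        self.bandwidth = bandwidth
        self.tau = tau
        self.kernel = kernel
        self.tau_grid = tau_grid
        self.fit_intercept = fit_intercept

    # -- internals ---------------------------------------------------------

    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(len(X)), X])
        return np.asarray(X, dtype=float)

    def _local_fit(
        self, A: np.ndarray, y: np.ndarray, coords: np.ndarray,
        targets: np.ndarray, h: float, tau: float, need_hat: bool,
    ) -> tuple[np.ndarray, np.ndarray]:
        """WLS at each target point; returns (betas, hat diag or zeros)."""
        n_t = len(targets)
        p = A.shape[1]
        betas = np.empty((n_t, p))
        hat = np.zeros(n_t)
        for i in range(n_t):
            w = st_weights(targets[i], coords, h, tau, self.kernel)
            Aw = A * w[:, None]
            AtWA = A.T @ Aw
            AtWy = Aw.T @ y
            try:
                c = np.linalg.cholesky(AtWA)
                beta = np.linalg.solve(c.T, np.linalg.solve(c, AtWy))
            except np.linalg.LinAlgError:
                cond_msg = (
                    f"weighted design is rank deficient at observation {i}; "
                    "increase the bandwidth h"
                )
                raise np.linalg.LinAlgError(cond_msg) from None
            betas[i] = beta
            if need_hat:
                # S_ii = A_i (AᵀWA)⁻¹ A_i w_i : own diagonal entry of the hat matrix
                hat[i] = w[i] * (A[i] @ np.linalg.solve(AtWA, A[i]))
        return betas, hat

    def _aicc(self, rss: float, n: int, tr_s: float) -> float:
        sigma2 = rss / n
        denom = n - 2.0 - tr_s
        if denom <= 0:
            return np.inf
        return n * np.log(sigma2) + n * np.log(2 * np.pi) + n * (n + tr_s) / denom

    def _score_bandwidth(self, A, y, coords, h, tau) -> float:
        try:
            betas, hat = self._local_fit(A, y, coords, coords, h, tau, need_hat=True)
        except np.linalg.LinAlgError:
            return np.inf
        fitted = (A * betas).sum(axis=1)
        rss = float(((y - fitted) ** 2).sum())
        return self._aicc(rss, len(y), float(hat.sum()))

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, coords=None):
        """Fit local coefficients at every observation.

        ``coords`` is an (n, 3) array of (u, v, t); it may also be passed as
        the first three columns of X if coords is None and X has >= 4
        columns with a leading '__coords__' marker — in practice pass it
        explicitly.
        """
        if coords is None:
            raise ValueError("GTWR.fit requires coords=(n, 3) array of (u, v, t)")
        X, y = check_X_y(X, y)
        coords = check_array(coords)
        if coords.shape != (len(y), 3):
            raise ValueError(f"coords must be (n, 3); got {coords.shape}")
        A = self._design(X)
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise ValueError("design matrix is globally rank deficient")

        h, tau = self.bandwidth, self.tau
        if h is None:
            h, tau, self.selection_warning_ = _select_h_tau(
                self, A, y, coords, tau_fixed=self.tau if self.tau is not None else None,
                tau_grid=self.tau_grid,
            )
        betas, hat = self._local_fit(A, y, coords, coords, h, tau, need_hat=True)

        self.bandwidth_, self.tau_ = float(h), float(tau)
        if self.fit_intercept:
            self.intercept_ = betas[:, 0]
            self.coef_ = betas[:, 1:]
        else:
            self.intercept_ = np.zeros(len(y))
            self.coef_ = betas
        self.fitted_ = (A * betas).sum(axis=1)
        self.residuals_ = y - self.fitted_
        self.hat_diag_ = hat
        self.hat_trace_ = float(hat.sum())
        rss = float((self.residuals_**2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - rss / tss if tss > 0 else np.nan
        self.aicc_ = self._aicc(rss, len(y), self.hat_trace_) if rss > 0 else -np.inf
        self._train_X_ = X
        self._train_y_ = y
        self._train_coords_ = coords
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, coords=None):
        """Predict at new points by refitting local coefficients there."""
        check_is_fitted(self, "coef_")
        if coords is None:
            raise ValueError("GTWR.predict requires coords")
        X = check_array(X)
        coords = check_array(coords)
        A_train = self._design(self._train_X_)
        A_new = self._design(X)
        betas, _ = self._local_fit(
            A_train, self._train_y_, self._train_coords_, coords,
            self.bandwidth_, self.tau_, need_hat=False,
        )
        return (A_new * betas).sum(axis=1)

    def local_coefficients(self, feature_names=None) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        names = feature_names or [f"x{j}" for j in range(self.coef_.shape[1])]
        df = pd.DataFrame(self.coef_, columns=names)
        df.insert(0, "intercept", self.intercept_)
        return df


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 60):
    """Minimize f on [lo, hi]; returns (x, f(x)). Deterministic."""
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if (b - a) < tol * (abs(a) + abs(b)) / 2 + 1e-12:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return (c, fc) if fc < fd else (d, fd)


def _select_h_tau(model: GTWR, A, y, coords, tau_fixed, tau_grid):
    """AICc-minimizing bandwidth via golden-section search, nested in a
    coarse τ grid when τ is not fixed."""
    uv = coords[:, :2]
    diam = float(np.sqrt(((uv.max(axis=0) - uv.min(axis=0)) ** 2).sum()))
    if diam == 0:
        diam = 1.0
    lo, hi = 0.02 * diam, 4.0 * diam
    taus = [tau_fixed] if tau_fixed is not None else list(tau_grid)
    best = (np.inf, None, None)
    for tau in taus:
        h, score = _golden_section(
            lambda h_: model._score_bandwidth(A, y, coords, h_, tau), lo, hi
        )
        if score < best[0]:
            best = (score, h, tau)
    warning = None
    if not np.isfinite(best[0]):
        warning = "AICc profile not finite anywhere on the search range"
        warnings.warn(warning, stacklevel=2)
        best = (np.inf, hi, taus[0])
    return best[1], best[2], warning


def select_bandwidth(
    X, y, coords, tau: float | None = None,
    tau_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    kernel: str = "gaussian",
) -> tuple[float, float]:
    """Standalone AICc bandwidth (and τ) selection; deterministic.

    Requires at least 10 observations for the effective-parameter count in
    AICc to be meaningful.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 10:
        raise ValueError("bandwidth selection needs at least 10 observations")
    model = GTWR(bandwidth=None, tau=tau, kernel=kernel, tau_grid=tau_grid)
    A = model._design(X)
    h, tau_sel, _ = _select_h_tau(
        model, A, np.asarray(y, dtype=float), np.asarray(coords, dtype=float),
        tau_fixed=tau, tau_grid=tau_grid,
    )
    return float(h), float(tau_sel)


def classify_coefficients(values, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin a local-coefficient surface into k ordered levels.

    Returns (labels 0..k-1 per value, bin edges). Fewer distinct values
    than bins collapses to the feasible number with a warning. The sign
    (positive vs negative driving) is read off the values themselves.
    """
    if k < 2:
        raise ValueError("need k >= 2 classes")
    v = np.asarray(values, dtype=float)
    qs = np.quantile(v, np.linspace(0, 1, k + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < k:
        warnings.warn(
            f"only {max(len(edges) - 1, 1)} distinct quantile bins available for k={k}",
            stacklevel=2,
        )
    if len(edges) < 2:
        return np.zeros(len(v), dtype=int), edges
    labels = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
    return labels, edges
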