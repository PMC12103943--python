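"""VIF screening, space-time kernel weights, GTWR fitting and bandwidth
selection, including recovery against the sealed synthetic truth."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from karsthealth import (
    GTWR,
    VIFScreener,
    classify_coefficients,
    select_bandwidth,
    st_weights,
    vif_screen,
)
from karsthealth.gtwr import vif_scores
from karsthealth.synthetic import generate_driver_panel, recovery_scenario
from _oracles import naive_vif

DRIVERS = ["PRE", "TEM", "RHU", "FVC", "NLI", "LUI"]


def fit_on_panel(panel, h, tau=1.0):
    X = panel[DRIVERS].to_numpy()
    y = panel["Y"].to_numpy()
    coords = panel[["u", "v", "t"]].to_numpy()
    return GTWR(bandwidth=h, tau=tau).fit(X, y, coords=coords), X, y, coords


class TestVif:
    def test_orthogonal_drivers_all_unity(self):
        n = 64
        X = np.zeros((n, 3))
        X[:, 0] = np.tile([1, -1], n // 2)
        X[:, 1] = np.tile([1, 1, -1, -1], n // 4)
        X[:, 2] = np.tile([1, 1, 1, 1, -1, -1, -1, -1], n // 8)
        assert vif_scores(X) == pytest.approx(np.ones(3))
        retained, _ = vif_screen(pd.DataFrame(X, columns=list("abc")))
        assert retained == list("abc")

    def test_duplicated_column_removed_first(self, rng):
        a = rng.standard_normal(50)
        df = pd.DataFrame({"a": a, "dup": a, "b": rng.standard_normal(50)})
        retained, report = vif_screen(df)
        assert "b" in retained
        assert len([c for c in retained if c in ("a", "dup")]) == 1
        assert np.isinf(report.loc[report["round"] == 0, "vif"]).sum() >= 2

    def test_correlated_triple_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(77)
        base = rng.standard_normal(200)
        X = np.column_stack(
            [base + 0.2 * rng.standard_normal(200) for _ in range(3)]
        )
        assert vif_scores(X) == pytest.approx(naive_vif(X), rel=1e-8)
        retained, _ = vif_screen(pd.DataFrame(X, columns=list("xyz")), threshold=7.5)
        assert len(retained) < 3

    def test_screener_transformer_contract(self, rng):
        a = rng.standard_normal(60)
        df = pd.DataFrame({"a": a, "dup": a + 1e-12, "b": rng.standard_normal(60)})
        sc = VIFScreener(threshold=7.5).fit(df)
        out = sc.transform(df)
        assert list(out.columns) == sc.retained_
        assert clone(sc).get_params()["threshold"] == 7.5


class TestStWeights:
    def test_tau_zero_ignores_time(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 5.0], [1.0, 0.0, 9.0]])
        w = st_weights(coords[0], coords, h=1.0, tau=0.0)
        assert w[1] == pytest.approx(1.0)  # co-located, different epoch
        assert w[2] == pytest.approx(np.exp(-1.0))

    def test_huge_bandwidth_flattens_weights(self):
        coords = np.random.default_rng(0).uniform(0, 1, size=(20, 3))
        w = st_weights(coords[0], coords, h=1e9, tau=1.0)
        assert w == pytest.approx(np.ones(20))

    def test_hand_evaluated_three_points(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 0.0, 2.0]])
        w = st_weights(coords[0], coords, h=5.0, tau=2.0)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(np.exp(-25.0 / 25.0))
        assert w[2] == pytest.approx(np.exp(-8.0 / 25.0))

    def test_bad_inputs_rejected(self):
        c = np.zeros((2, 3))
        with pytest.raises(ValueError):
            st_weights(c[0], c, h=0.0, tau=1.0)
        with pytest.raises(ValueError):
            st_weights(c[0], c, h=1.0, tau=-1.0)
        with pytest.raises(ValueError):
            st_weights(np.array([np.nan, 0, 0]), c, h=1.0, tau=1.0)


class TestGtwrFit:
    def test_infinite_bandwidth_matches_ols(self):
        rng = np.random.default_rng(5)
        n = 80
        coords = np.column_stack([rng.uniform(0, 1, (n, 2)), rng.integers(0, 5, n)])
        X = rng.standard_normal((n, 3))
        y = 0.5 + X @ [1.0, -2.0, 0.7] + 0.1 * rng.standard_normal(n)
        m = GTWR(bandwidth=1e6, tau=1.0).fit(X, y, coords=coords)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        for i in range(n):
            assert np.abs(m.intercept_[i] - ols[0]) / abs(ols[0]) < 1e-6
            assert np.abs(m.coef_[i] - ols[1:]).max() / np.abs(ols[1:]).max() < 1e-6

    def test_noiseless_constant_coefficients_recovered_exactly(self):
        sc = recovery_scenario(seed=3, strong_variation=False)
        sc.noise_sd = 0.0
        panel, truth = generate_driver_panel(sc)
        m, *_ = fit_on_panel(panel, h=0.3)
        want = truth.coefficients[DRIVERS].to_numpy()
        assert m.coef_ == pytest.approx(want, abs=1e-8)
        assert m.residuals_ == pytest.approx(np.zeros(len(panel)), abs=1e-8)

    def test_tau_zero_single_epoch_equals_gwr(self):
        # with one time slice, the time term is identically zero: fits with
        # tau = 0 and any tau > 0 must coincide (pure GWR)
        rng = np.random.default_rng(9)
        n = 60
        coords = np.column_stack([rng.uniform(0, 1, (n, 2)), np.zeros(n)])
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ [1.5, -0.5] + (0.5 * coords[:, 0]) * X[:, 0]
        a = GTWR(bandwidth=0.3, tau=0.0).fit(X, y, coords=coords)
        b = GTWR(bandwidth=0.3, tau=7.3).fit(X, y, coords=coords)
        assert a.coef_ == pytest.approx(b.coef_)

    def test_fitted_plus_residual_reconstructs_response(self):
        sc = recovery_scenario(seed=1)
        panel, _ = generate_driver_panel(sc)
        m, _, y, _ = fit_on_panel(panel, h=0.3)
        assert m.fitted_ + m.residuals_ == pytest.approx(y)
        assert np.isfinite(m.aicc_)

    def test_local_weighted_residual_orthogonality(self):
        # at each target the weighted residuals are orthogonal to the
        # weighted design columns
        rng = np.random.default_rng(11)
        n = 40
        coords = np.column_stack([rng.uniform(0, 1, (n, 2)), rng.integers(0, 3, n)])
        X = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        m = GTWR(bandwidth=0.4, tau=0.5).fit(X, y, coords=coords)
        A = np.column_stack([np.ones(n), X])
        for i in range(0, n, 7):
            w = st_weights(coords[i], coords, 0.4, 0.5)
            beta = np.concatenate([[m.intercept_[i]], m.coef_[i]])
            resid = y - A @ beta
            assert A.T @ (w * resid) == pytest.approx(np.zeros(3), abs=1e-8)

    def test_spatially_varying_coefficient_beats_ols(self):
        sc = recovery_scenario(seed=4, strong_variation=True)
        panel, truth = generate_driver_panel(sc)
        m, X, y, coords = fit_on_panel(panel, h=0.25)
        A = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        true_b1 = truth.coefficients["PRE"].to_numpy()
        j = DRIVERS.index("PRE")
        rmse_local = np.sqrt(np.mean((m.coef_[:, j] - true_b1) ** 2))
        rmse_ols = np.sqrt(np.mean((ols[1 + j] - true_b1) ** 2))
        assert rmse_local < 0.5 * rmse_ols

    def test_rank_deficiency_reported(self):
        n = 30
        rng = np.random.default_rng(2)
        coords = np.column_stack([rng.uniform(0, 1, (n, 2)), np.zeros(n)])
        X = np.column_stack([rng.standard_normal(n)] * 2)  # identical columns
        y = rng.standard_normal(n)
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            GTWR(bandwidth=0.3, tau=0.0).fit(X, y, coords=coords)


class TestBandwidthSelection:
    def _panel(self, strong, seed):
        sc = recovery_scenario(seed=seed, strong_variation=strong)
        sc.n_zones = 36  # keep the nested search cheap
        panel, _ = generate_driver_panel(sc)
        return panel

    def test_varying_coefficients_select_smaller_bandwidth(self):
        strong = self._panel(strong=True, seed=6)
        flat = self._panel(strong=False, seed=6)
        h_strong, _ = select_bandwidth(
            strong[DRIVERS], strong["Y"], strong[["u", "v", "t"]], tau=1.0
        )
        h_flat, _ = select_bandwidth(
            flat[DRIVERS], flat["Y"], flat[["u", "v", "t"]], tau=1.0
        )
        assert h_strong < h_flat

    def test_selected_bandwidth_beats_random_probes(self):
        panel = self._panel(strong=True, seed=8)
        X = panel[DRIVERS].to_numpy()
        y = panel["Y"].to_numpy()
        coords = panel[["u", "v", "t"]].to_numpy()
        h, tau = select_bandwidth(X, y, coords, tau=1.0)
        model = GTWR(bandwidth=h, tau=tau).fit(X, y, coords=coords)
        rng = np.random.default_rng(0)
        for h_probe in rng.uniform(0.05, 3.0, size=10):
            probe = GTWR(bandwidth=h_probe, tau=tau).fit(X, y, coords=coords)
            assert model.aicc_ <= probe.aicc_ + 1e-6

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            select_bandwidth(np.ones((5, 2)), np.ones(5), np.zeros((5, 3)))


class TestClassifyCoefficients:
    def test_eight_values_four_even_bins(self):
        labels, edges = classify_coefficients(np.arange(1.0, 9.0), k=4)
        assert np.bincount(labels).tolist() == [2, 2, 2, 2]

    def test_all_equal_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            labels, _ = classify_coefficients(np.ones(10), k=4)
        assert set(labels) == {0}

    def test_bin_edges_match_quantile_oracle(self, rng):
        v = rng.standard_normal(200)
        _, edges = classify_coefficients(v, k=4)
        assert edges == pytest.approx(np.quantile(v, [0, 0.25, 0.5, 0.75, 1.0]))
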