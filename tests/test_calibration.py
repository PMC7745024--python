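import math

import numpy as np
import pytest

from pmcal import (
    calibrate,
    fit_global,
    fit_local,
    fit_spatial,
    gaussian_weight,
    loo_rmse_spatial,
    select_bandwidth,
)
from pmcal.errors import ConfigurationError, SingularFitError, UnderdeterminedFitError

from conftest import make_obs, make_pairs, wls_oracle


class TestGaussianWeight:
    def test_unity_at_zero_distance(self):
        assert gaussian_weight(0.0, 1000.0) == 1.0

    def test_analytic_values(self):
        b = 1234.5
        assert gaussian_weight(b, b) == pytest.approx(math.exp(-1))
        assert gaussian_weight(2 * b, b) == pytest.approx(math.exp(-4))

    def test_strictly_decreasing(self):
        d = np.linspace(0, 5e4, 200)
        w = gaussian_weight(d, 7000.0)
        assert np.all(np.diff(w) < 0)
        assert np.all((w > 0) & (w <= 1))

    @pytest.mark.parametrize("b", [0.0, -10.0])
    def test_nonpositive_bandwidth_rejected(self, b):
        with pytest.raises(ValueError):
            gaussian_weight(100.0, b)


class TestGlobalFit:
    def test_exact_line_recovered(self, rng):
        x = rng.uniform(5, 80, 12)
        pairs = make_pairs(rng.uniform(0, 1e5, (12, 2)), 2 * x + 1, x)
        model = fit_global(pairs)
        np.testing.assert_allclose(model.beta, [1.0, 2.0], atol=1e-10)

    def test_constant_covariate_is_singular(self, rng):
        pairs = make_pairs(rng.uniform(0, 1e5, (10, 2)),
                           rng.uniform(10, 60, 10), np.full(10, 42.0))
        with pytest.raises(SingularFitError):
            fit_global(pairs)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(5, 80, 20)
        y = 0.7 * x + 5 + rng.normal(0, 3, 20)
        pairs = make_pairs(rng.uniform(0, 1e5, (20, 2)), y, x)
        model = fit_global(pairs)
        X = np.column_stack([np.ones(20), x])
        expected = wls_oracle(X, y, np.ones(20))
        np.testing.assert_allclose(model.beta, expected, rtol=1e-10)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(5, 80, 30)
        y = 0.6 * x + 8 + rng.normal(0, 4, 30)
        pairs = make_pairs(rng.uniform(0, 1e5, (30, 2)), y, x)
        model = fit_global(pairs)
        ref = sm.OLS(y, sm.add_constant(x)).fit().params
        np.testing.assert_allclose(model.beta, ref, rtol=1e-9)


class TestLocalFit:
    def test_large_bandwidth_limit_equals_global(self, rng):
        x = rng.uniform(5, 80, 25)
        y = 0.8 * x + 3 + rng.normal(0, 2, 25)
        anchors = rng.uniform(0, 5e4, (25, 2))
        pairs = make_pairs(anchors, y, x)
        glob = fit_global(pairs).beta
        beta = fit_local(anchors[7], pairs, b=1e9)
        np.testing.assert_allclose(beta, glob, rtol=1e-6)

    def test_matches_weighted_oracle_and_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(5, 80, 40)
        y = 0.5 * x + 10 + rng.normal(0, 3, 40)
        anchors = rng.uniform(0, 3e4, (40, 2))
        pairs = make_pairs(anchors, y, x)
        target = np.array([1.2e4, 0.8e4])
        b = 9000.0
        beta = fit_local(target, pairs, b)
        d = np.hypot(*(anchors - target).T)
        w = np.exp(-((d / b) ** 2))
        X = np.column_stack([np.ones(40), x])
        np.testing.assert_allclose(beta, wls_oracle(X, y, w), rtol=1e-8)
        ref = sm.WLS(y, X, weights=w).fit().params
        np.testing.assert_allclose(beta, ref, rtol=1e-8)

    def test_degenerate_local_covariate_is_handled(self, rng, caplog):
        """All pairs sharing one x near the target: the rank-1 normal matrix
        must be ridged (logged) or rejected, never return garbage."""
        anchors = rng.uniform(0, 1e4, (10, 2))
        pairs = make_pairs(anchors, rng.uniform(10, 60, 10), np.full(10, 42.0))
        with caplog.at_level("INFO", logger="pmcal.calibration"):
            try:
                beta = fit_local(anchors[0], pairs, b=5000.0)
            except (SingularFitError, UnderdeterminedFitError):
                return
        assert np.all(np.isfinite(beta))
        assert any("ridge" in r.message for r in caplog.records)

    def test_too_few_effective_neighbors_raises(self, rng):
        # target so far away that every weight underflows below the floor
        anchors = rng.uniform(0, 1e3, (10, 2))
        pairs = make_pairs(anchors, rng.uniform(10, 60, 10),
                           rng.uniform(10, 60, 10))
        with pytest.raises(UnderdeterminedFitError):
            fit_local([1e7, 1e7], pairs, b=1e3)


class TestSpatialFit:
    def test_one_coefficient_vector_per_anchor(self, rng):
        n = 69
        x = rng.uniform(5, 80, n)
        pairs = make_pairs(rng.uniform(0, 2e5, (n, 2)),
                           0.6 * x + 5 + rng.normal(0, 2, n), x)
        model = fit_spatial(pairs, b=5e4)
        assert model.local_coefficients.shape == (n, 2)

    def test_homogeneous_truth_gives_near_global_slopes(self, rng):
        n = 60
        x = rng.uniform(5, 80, n)
        y = 0.7 * x + 4 + rng.normal(0, 1, n)
        pairs = make_pairs(rng.uniform(0, 1e5, (n, 2)), y, x)
        glob = fit_global(pairs).beta
        model = fit_spatial(pairs, b=6e4)
        slopes = model.local_coefficients[:, 1]
        assert np.all(np.abs(slopes - glob[1]) < 0.15)

    def test_slope_surface_varies_smoothly(self, rng):
        """On heterogeneous data, nearby anchors get more similar slopes
        than distant anchors on average."""
        n = 80
        anchors = rng.uniform(0, 1e5, (n, 2))
        x = rng.uniform(10, 80, n)
        slope_true = 0.4 + 0.6 * anchors[:, 0] / 1e5
        y = slope_true * x + 5
        pairs = make_pairs(anchors, y, x)
        model = fit_spatial(pairs, b=2.5e4)
        slopes = model.local_coefficients[:, 1]
        d = np.hypot(anchors[:, 0, None] - anchors[None, :, 0],
                     anchors[:, 1, None] - anchors[None, :, 1])
        ds = np.abs(slopes[:, None] - slopes[None, :])
        iu = np.triu_indices(n, 1)
        near = d[iu] < np.percentile(d[iu], 25)
        far = d[iu] > np.percentile(d[iu], 75)
        assert ds[iu][near].mean() < ds[iu][far].mean()


class TestBandwidthSelection:
    def test_single_candidate_returned(self, rng):
        n = 30
        x = rng.uniform(5, 80, n)
        pairs = make_pairs(rng.uniform(0, 1e5, (n, 2)), 0.7 * x + 2, x)
        assert select_bandwidth(pairs, [5000.0]) == 5000.0

    def _loo_oracle(self, pairs, b):
        """Independent LOO loop using the explicit-inverse WLS estimator.

        Weights are normalised by the nearest anchor's weight (WLS is
        invariant to weight scaling); a singular fold marks the bandwidth
        infeasible (infinite score)."""
        X = np.column_stack([np.ones(pairs.n), pairs.X[:, 0]])
        y, anchors = pairs.y, pairs.anchors
        errs = []
        for i in range(pairs.n):
            mask = np.arange(pairs.n) != i
            d = np.hypot(*(anchors[mask] - anchors[i]).T)
            w = np.exp(-(d ** 2 - d.min() ** 2) / b ** 2)
            try:
                beta = wls_oracle(X[mask], y[mask], w)
            except np.linalg.LinAlgError:
                return float("inf")
            if not np.all(np.isfinite(beta)):
                return float("inf")
            errs.append(y[i] - X[i] @ beta)
        return float(np.sqrt(np.mean(np.square(errs))))

    def test_constant_coefficients_select_largest(self, rng):
        n = 40
        anchors = rng.uniform(0, 2e5, (n, 2))
        x = rng.uniform(5, 80, n)
        y = 0.7 * x + 4 + rng.normal(0, 2, n)
        pairs = make_pairs(anchors, y, x)
        cands = [2e3, 2e4, 2e5]
        assert select_bandwidth(pairs, cands) == 2e5
        scores = {b: self._loo_oracle(pairs, b) for b in cands}
        assert min(scores, key=scores.get) == 2e5

    def test_varying_slope_selects_smaller(self, rng):
        n = 60
        anchors = rng.uniform(0, 2e5, (n, 2))
        x = rng.uniform(5, 80, n)
        slope = 0.3 + 1.2 * anchors[:, 0] / 2e5
        y = slope * x + 4 + rng.normal(0, 1, n)
        pairs = make_pairs(anchors, y, x)
        cands = [2e3, 2e4, 2e5]
        chosen = select_bandwidth(pairs, cands)
        assert chosen < 2e5
        scores = {b: self._loo_oracle(pairs, b) for b in cands}
        assert chosen == min(scores, key=scores.get)

    def test_agrees_with_oracle_scores(self, rng):
        n = 35
        anchors = rng.uniform(0, 1e5, (n, 2))
        x = rng.uniform(5, 80, n)
        y = (0.5 + 0.5 * anchors[:, 1] / 1e5) * x + 6 + rng.normal(0, 2, n)
        pairs = make_pairs(anchors, y, x)
        for b in [1e4, 5e4]:
            assert loo_rmse_spatial(pairs, b) == pytest.approx(
                self._loo_oracle(pairs, b), rel=1e-8)


class TestCalibrate:
    def test_identity_model_returns_input(self, rng):
        from pmcal import GlobalCalibration
        sensors = make_obs(rng.uniform(0, 1e4, (5, 2)), [10, 20, 30, 40, 50.0])
        model = GlobalCalibration(beta=np.array([0.0, 1.0]), n_train=10)
        out = calibrate(model, sensors)
        np.testing.assert_allclose(out.pm25, sensors.pm25)

    def test_affine_model_arithmetic(self):
        from pmcal import GlobalCalibration
        sensors = make_obs([[0, 0]], [100.0])
        model = GlobalCalibration(beta=np.array([2.8, 0.93]), n_train=69)
        out = calibrate(model, sensors)
        assert out.pm25[0] == pytest.approx(95.8)

    def test_negative_predictions_floored(self, rng):
        from pmcal import GlobalCalibration
        sensors = make_obs(rng.uniform(0, 1e4, (3, 2)), [1.0, 2.0, 100.0])
        model = GlobalCalibration(beta=np.array([-10.0, 1.0]), n_train=10)
        out = calibrate(model, sensors)
        np.testing.assert_allclose(out.pm25, [0.0, 0.0, 90.0])

    def test_spatial_at_anchor_matches_stored_coefficients(self, rng):
        n = 30
        anchors = rng.uniform(0, 1e5, (n, 2))
        x = rng.uniform(5, 80, n)
        y = (0.4 + 0.8 * anchors[:, 0] / 1e5) * x + 3 + rng.normal(0, 1, n)
        pairs = make_pairs(anchors, y, x)
        model = fit_spatial(pairs, b=3e4)
        sensors = make_obs(anchors[:5], x[:5])
        out = calibrate(model, sensors)
        stored = model.local_coefficients[:5]
        expected = stored[:, 0] + stored[:, 1] * x[:5]
        np.testing.assert_allclose(out.pm25, np.maximum(expected, 0), rtol=1e-10)

    def test_missing_covariate_is_configuration_error(self, rng):
        from pmcal import GlobalCalibration
        sensors = make_obs(rng.uniform(0, 1e4, (3, 2)), [10.0, 20.0, 30.0])
        model = GlobalCalibration(beta=np.array([0.0, 1.0, 0.1]), n_train=10,
                                  covariate_names=("pm25", "rh"))
        with pytest.raises(ConfigurationError):
            calibrate(model, sensors)


class TestSerialization:
    def test_spatial_model_round_trips(self, rng, tmp_path):
        from pmcal import SpatialCalibration
        n = 20
        anchors = rng.uniform(0, 1e5, (n, 2))
        x = rng.uniform(5, 80, n)
        pairs = make_pairs(anchors, 0.7 * x + 2 + rng.normal(0, 1, n), x)
        model = fit_spatial(pairs, b=4e4)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = SpatialCalibration.from_json(p)
        assert back.bandwidth == model.bandwidth
        np.testing.assert_allclose(back.local_coefficients,
                                   model.local_coefficients)
        target = rng.uniform(0, 1e5, (3, 2))
        np.testing.assert_allclose(back.coefficients_at(target),
                                   model.coefficients_at(target), rtol=1e-12)
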