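import numpy as np
import pytest

from canomix.design import DesignMatrix, lhs_maximin
from canomix.kriging import fit_kriging, kriging_predict, load_model, save_model


def smooth_2d(x):
    return np.sin(2 * np.pi * x[:, 0]) + np.sin(2 * np.pi * x[:, 1])


@pytest.fixture(scope="module")
def interp_model():
    design = lhs_maximin(40, [(0.0, 1.0)] * 2, seed=1)
    y = smooth_2d(design.points)
    return design, y, fit_kriging(design, y, nugget=0.0, seed=1)


class TestFit:
    def test_constant_response_flagged(self):
        design = lhs_maximin(12, [(0.0, 1.0)] * 2, seed=0)
        model = fit_kriging(design, np.full(12, 3.0))
        assert model.constant
        mean, sd = model.predict(np.array([[0.4, 0.9]]))
        assert mean[0] == pytest.approx(3.0)
        assert sd[0] == pytest.approx(0.0, abs=1e-9)

    def test_nan_response_rejected(self):
        design = lhs_maximin(12, [(0.0, 1.0)] * 2, seed=0)
        y = np.zeros(12)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_kriging(design, y)

    def test_too_few_points_rejected(self):
        design = lhs_maximin(3, [(0.0, 1.0)] * 2, seed=0)
        with pytest.raises(ValueError):
            fit_kriging(design, np.zeros(3))

    def test_zero_nugget_interpolates(self, interp_model):
        design, y, model = interp_model
        mean, _ = kriging_predict(model, design.points)
        assert np.max(np.abs(mean - y)) <= 1e-6

    def test_prediction_within_nugget_at_training_points(self):
        # noisy data: predictions at training points stay within the
        # estimated noise band
        rng = np.random.default_rng(3)
        design = lhs_maximin(60, [(0.0, 1.0)] * 2, seed=3)
        y = smooth_2d(design.points) + rng.normal(0, 0.05, 60)
        model = fit_kriging(design, y, seed=3)
        mean, _ = model.predict(design.points)
        assert np.max(np.abs(mean - y)) <= 3.0 * np.sqrt(model.nugget) + 1e-6

    def test_loo_rmse_on_polynomial(self):
        # leave-one-out refits on a smooth 3-D polynomial: RMSE below 5% of
        # the output range
        design = lhs_maximin(60, [(0.0, 1.0)] * 3, seed=5)
        x = design.points
        y = x[:, 0] ** 2 + 0.5 * x[:, 1] * x[:, 2] + x[:, 2]
        errs = []
        for i in range(0, 60, 6):  # every 6th point keeps the test quick
            keep = np.ones(60, dtype=bool)
            keep[i] = False
            sub = DesignMatrix(
                points=x[keep], bounds=design.bounds,
                dim_names=design.dim_names, seed=0, kind="generic",
            )
            m = fit_kriging(sub, y[keep], nugget=0.0, n_restarts=2, seed=i)
            pred, _ = m.predict(x[i : i + 1])
            errs.append(pred[0] - y[i])
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 0.05 * np.ptp(y)


class TestPredict:
    def test_sd_nonnegative_and_deterministic(self, interp_model):
        _, _, model = interp_model
        pts = np.random.default_rng(0).uniform(size=(30, 2))
        m1, s1 = model.predict(pts)
        m2, s2 = model.predict(pts)
        assert np.all(s1 >= 0)
        np.testing.assert_array_equal(m1, m2)

    def test_sd_smaller_at_training_point_than_in_gap(self, interp_model):
        design, _, model = interp_model
        _, sd_train = model.predict(design.points[:1])
        # centroid of the largest empty region: crude grid search
        grid = np.random.default_rng(1).uniform(size=(400, 2))
        from scipy.spatial.distance import cdist

        gaps = cdist(grid, design.points).min(axis=1)
        far = grid[np.argmax(gaps)][None, :]
        _, sd_far = model.predict(far)
        assert sd_train[0] <= sd_far[0]

    def test_far_extrapolation_returns_to_trend(self, interp_model):
        design, y, model = interp_model
        mean, _ = model.predict(np.array([[50.0, 50.0]]))
        assert mean[0] == pytest.approx(np.mean(y), abs=0.1)

    def test_dimension_mismatch_rejected(self, interp_model):
        _, _, model = interp_model
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 3)))

    def test_rescaling_invariance(self):
        """Affine rescaling of the input bounds must not change predictions."""
        base = lhs_maximin(30, [(0.0, 1.0)] * 2, seed=7)
        y = smooth_2d(base.points)
        scaled = DesignMatrix(
            points=base.points * np.array([100.0, 0.01]) + np.array([-50.0, 3.0]),
            bounds=np.array([(-50.0, 50.0), (3.0, 3.01)]),
            dim_names=base.dim_names, seed=7, kind="generic",
        )
        m1 = fit_kriging(base, y, nugget=0.0, n_restarts=2, seed=7)
        m2 = fit_kriging(scaled, y, nugget=0.0, n_restarts=2, seed=7)
        q = np.random.default_rng(2).uniform(size=(20, 2))
        p1, _ = m1.predict(q)
        p2, _ = m2.predict(q * np.array([100.0, 0.01]) + np.array([-50.0, 3.0]))
        np.testing.assert_allclose(p1, p2, rtol=1e-5, atol=1e-8)


class TestRecoveryAndSerialization:
    def test_length_scale_recovery(self):
        """Data from a GP with known anisotropic length-scales: the fitted
        scales land within a factor of 2 in at least 8 of 10 replicates."""
        from sklearn.gaussian_process.kernels import Matern

        true_ls = np.array([0.2, 0.6])
        kern = Matern(length_scale=true_ls, nu=2.5)
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            x = rng.uniform(size=(80, 2))
            k = kern(x)
            y = rng.multivariate_normal(np.zeros(80), k + 1e-10 * np.eye(80))
            design = DesignMatrix(
                points=x, bounds=np.array([(0.0, 1.0)] * 2),
                dim_names=("a", "b"), seed=rep, kind="generic",
            )
            model = fit_kriging(design, y, nugget=0.0, n_restarts=3, seed=rep)
            ratio = model.length_scales / true_ls
            if np.all((ratio > 0.5) & (ratio < 2.0)):
                hits += 1
        assert hits >= 8

    def test_json_round_trip(self, tmp_path, interp_model):
        design, y, model = interp_model
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        pts = np.random.default_rng(4).uniform(size=(15, 2))
        m1, s1 = model.predict(pts)
        m2, s2 = back.predict(pts)
        np.testing.assert_allclose(m1, m2, rtol=1e-10)
        np.testing.assert_allclose(s1, s2, rtol=1e-8, atol=1e-10)
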