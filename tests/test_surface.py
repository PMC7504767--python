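import numpy as np
import pytest

from alsim import PotencySurfaceGPR, fit_surface, evaluate_surface
from alsim.datatypes import PotencyRaster


def smooth_sample(rng, n=200, noise_sd=0.01):
    """Sample f(x, y) = sin x + cos y on [0, 3]^2 with Gaussian noise."""
    X = rng.random((n, 2)) * 3.0
    f = np.sin(X[:, 0]) + np.cos(X[:, 1])
    return X, f + rng.normal(0, noise_sd, n) + 6.0  # shift into a pKi-like range


class TestFitSurface:
    def test_constant_potency_reproduced(self, rng):
        X = rng.random((30, 2))
        y = np.full(30, 7.3)
        model = fit_surface(X, y)
        pred = model.predict(rng.random((20, 2)))
        assert np.allclose(pred, 7.3, atol=1e-3)

    def test_smooth_function_recovered_at_held_out_points(self):
        rng = np.random.default_rng(0)
        X, y = smooth_sample(rng, n=200, noise_sd=0.01)
        model = fit_surface(X, y)
        Xt = rng.random((50, 2)) * 2.6 + 0.2  # interior held-out points
        truth = np.sin(Xt[:, 0]) + np.cos(Xt[:, 1]) + 6.0
        assert np.abs(model.predict(Xt) - truth).max() < 0.1

    def test_training_residuals_within_noise_bound(self):
        rng = np.random.default_rng(1)
        X, y = smooth_sample(rng, n=150, noise_sd=0.1)
        model = fit_surface(X, y)
        resid = np.abs(model.predict(X) - y)
        assert np.mean(resid <= 2 * model.noise_std_) > 0.9

    def test_selected_alpha_maximizes_lml(self):
        rng = np.random.default_rng(2)
        X, y = smooth_sample(rng, n=80, noise_sd=0.1)
        model = fit_surface(X, y)
        assert len(model.alpha_candidates_) == 10
        assert model.alpha_candidates_[0] == pytest.approx(1e-7)
        assert model.alpha_candidates_[-1] == pytest.approx(1e-1)
        best = model.log_marginal_likelihoods_.max()
        i = int(np.argmax(model.log_marginal_likelihoods_))
        assert model.alpha_ == pytest.approx(model.alpha_candidates_[i])
        assert np.all(model.log_marginal_likelihoods_ <= best)

    def test_rmse_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        Xt = rng.random((60, 2)) * 2.6 + 0.2
        truth = np.sin(Xt[:, 0]) + np.cos(Xt[:, 1]) + 6.0
        rmses = []
        for noise in (0.5, 0.15, 0.02):
            X, y = smooth_sample(np.random.default_rng(10), n=150, noise_sd=noise)
            model = fit_surface(X, y)
            rmses.append(float(np.sqrt(np.mean((model.predict(Xt) - truth) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X, y = smooth_sample(rng, n=60)
        a = fit_surface(X, y)
        b = fit_surface(X, y)
        grid = np.random.default_rng(5).random((30, 2)) * 3
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_degenerate_coordinates_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_surface(X, np.arange(10.0))

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="differ"):
            fit_surface(rng.random((10, 2)), np.arange(9.0))


class TestEvaluateSurface:
    def test_constant_model_constant_raster(self, rng):
        X = rng.random((20, 2))
        model = fit_surface(X, np.full(20, 6.1))
        raster = evaluate_surface(model, width=28, height=30)
        assert raster.values.shape == (30, 28)
        assert np.allclose(raster.values, 6.1, atol=1e-3)

    def test_default_extent_covers_training_with_margin(self, rng):
        X = rng.random((30, 2))
        model = fit_surface(X, rng.uniform(5, 8, 30))
        xmin, xmax, ymin, ymax = model.extent_
        assert xmin < X[:, 0].min() and xmax > X[:, 0].max()
        assert ymin < X[:, 1].min() and ymax > X[:, 1].max()

    def test_pixel_nearest_training_point_matches_prediction(self):
        rng = np.random.default_rng(6)
        X, y = smooth_sample(rng, n=120, noise_sd=0.01)
        model = fit_surface(X, y)
        raster = evaluate_surface(model)
        xmin, xmax, ymin, ymax = raster.extent
        for i in rng.integers(0, 120, 10):
            col = int((X[i, 0] - xmin) / (xmax - xmin) * raster.width)
            row = int((ymax - X[i, 1]) / (ymax - ymin) * raster.height)
            assert raster.values[row, col] == pytest.approx(
                model.predict(X[i:i + 1])[0], abs=0.05)

    def test_resolution_consistency(self):
        rng = np.random.default_rng(7)
        X, y = smooth_sample(rng, n=100, noise_sd=0.01)
        model = fit_surface(X, y)
        lo = evaluate_surface(model, width=70, height=75)
        hi = evaluate_surface(model, width=140, height=150)
        down = hi.values.reshape(75, 2, 70, 2).mean(axis=(1, 3))
        assert np.abs(down - lo.values).max() < 0.05

    def test_raster_orientation(self):
        # potency rising with y must put the largest values in row 0 (top)
        rng = np.random.default_rng(8)
        X = rng.random((80, 2))
        model = fit_surface(X, 5.0 + 3.0 * X[:, 1])
        raster = evaluate_surface(model, width=28, height=30)
        assert raster.values[0].mean() > raster.values[-1].mean()

    def test_bad_extent_rejected(self, rng):
        X = rng.random((20, 2))
        model = fit_surface(X, rng.uniform(5, 8, 20))
        with pytest.raises(ValueError, match="extent"):
            evaluate_surface(model, extent=(0, 0, 0, 1))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        X, y = smooth_sample(rng, n=60)
        model = fit_surface(X, y)
        path = tmp_path / "surface.json"
        model.save(path)
        loaded = PotencySurfaceGPR.load(path)
        grid = rng.random((40, 2)) * 3
        assert np.allclose(model.predict(grid), loaded.predict(grid), atol=1e-10)
        assert loaded.alpha_ == model.alpha_
        assert loaded.extent_ == pytest.approx(model.extent_)

    def test_load_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"something": 1}')
        with pytest.raises(ValueError, match="not a surface archive"):
            PotencySurfaceGPR.load(path)


def test_raster_type_invariants():
    with pytest.raises(ValueError, match="non-finite"):
        PotencyRaster(values=np.array([[np.inf]]), extent=(0, 1, 0, 1))
    with pytest.raises(ValueError, match="area"):
        PotencyRaster(values=np.zeros((2, 2)), extent=(1, 1, 0, 1))
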