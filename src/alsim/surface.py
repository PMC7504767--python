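"""Potency surface interpolation by Gaussian-process regression.

The third dimension of the activity landscape is an interpolated potency
surface over the 2D chemical-space projection.  A zero-mean GP with a
"Sum of Matern and White" covariance is fitted to mean-centered pKi
values; the regularization parameter alpha (extra diagonal noise) is
selected from ten log-spaced candidates spanning [1e-7, 1e-1] by maximum
log marginal likelihood, with the kernel hyperparameters re-optimized at
each candidate.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.utils.validation import check_is_fitted

from .datatypes import PotencyRaster
from .config import IMAGE_WIDTH, IMAGE_HEIGHT, ALPHA_BOUNDS, N_ALPHA_CANDIDATES


def _margin_extent(coords: np.ndarray, margin: float = 0.05):
    """Bounding box of the coordinates expanded by ``margin`` per side."""
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    dx = (xmax - xmin) or 1.0  # degenerate spans get a unit margin base
    dy = (ymax - ymin) or 1.0
    return (xmin - margin * dx, xmax + margin * dx,
            ymin - margin * dy, ymax + margin * dy)


class PotencySurfaceGPR(BaseEstimator, RegressorMixin):
    """Gaussian-process potency surface over 2D chemical-space coordinates.

    Parameters
    ----------
    nu : float, default=1.5
        Matern smoothness parameter.
    length_scale : float, default=1.0
        Initial Matern length scale (projection-coordinate units).
    length_scale_bounds : pair of float, default=(1e-2, 1e2)
        Optimization bounds for the length scale.
    noise_level : float, default=1e-2
        Initial White-kernel noise variance (pKi^2 units).
    noise_level_bounds : pair of float, default=(1e-5, 1.0)
        Optimization bounds for the White-kernel noise.
    alpha_bounds : pair of float, default=(1e-7, 1e-1)
        Range from which the diagonal regularization alpha is selected.
    n_alpha_candidates : int, default=10
        Number of log-spaced alpha candidates evaluated.

    Attributes
    ----------
    gpr_ : sklearn.gaussian_process.GaussianProcessRegressor
        The fitted GP at the selected alpha.
    alpha_ : float
        Selected regularization value.
    offset_ : float
        Mean potency subtracted before fitting (the zero-mean prior is
        applied to centered targets) and added back at prediction.
    alpha_candidates_ : ndarray of shape (n_alpha_candidates,)
        The evaluated alpha grid.
    log_marginal_likelihoods_ : ndarray of shape (n_alpha_candidates,)
        Log marginal likelihood at each candidate (after hyperparameter
        optimization); ``alpha_`` attains the maximum.
    """

    def __init__(self, nu: float = 1.5, length_scale: float = 1.0,
                 length_scale_bounds=(1e-2, 1e2), noise_level: float = 1e-2,
                 noise_level_bounds=(1e-5, 1.0), alpha_bounds=ALPHA_BOUNDS,
                 n_alpha_candidates: int = N_ALPHA_CANDIDATES):
        self.nu = nu
        self.length_scale = length_scale
        self.length_scale_bounds = length_scale_bounds
        self.noise_level = noise_level
        self.noise_level_bounds = noise_level_bounds
        self.alpha_bounds = alpha_bounds
        self.n_alpha_candidates = n_alpha_candidates

    def _make_kernel(self, theta: np.ndarray | None = None):
        kernel = Matern(
            length_scale=self.length_scale,
            length_scale_bounds=self.length_scale_bounds,
            nu=self.nu,
        ) + WhiteKernel(
            noise_level=self.noise_level,
            noise_level_bounds=self.noise_level_bounds,
        )
        if theta is not None:
            kernel.theta = theta
        return kernel

    def fit(self, X, y):
        """Fit the surface to coordinates X (n, 2) and pKi values y (n,)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"expected (n, 2) coordinates, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("coordinate and potency counts differ")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        if np.allclose(X, X[0], atol=1e-12):
            raise ValueError("degenerate coordinates: all training points coincide")

        self.offset_ = float(y.mean())
        y_centered = y - self.offset_

        lo, hi = self.alpha_bounds
        candidates = np.logspace(np.log10(lo), np.log10(hi), self.n_alpha_candidates)
        lmls = np.empty_like(candidates)
        best = None
        theta = None  # warm-start hyperparameters along the alpha grid
        for i, alpha in enumerate(candidates):
            gpr = GaussianProcessRegressor(
                kernel=self._make_kernel(theta), alpha=float(alpha),
                normalize_y=False,
            )
            with warnings.catch_warnings():
                # hyperparameters legitimately rest on their bounds for
                # flat or very noisy surfaces; the bounds are intentional
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(X, y_centered)
            theta = gpr.kernel_.theta
            lmls[i] = gpr.log_marginal_likelihood_value_
            if best is None or lmls[i] > best[0]:
                best = (lmls[i], float(alpha), gpr)

        self.alpha_candidates_ = candidates
        self.log_marginal_likelihoods_ = lmls
        self.alpha_ = best[1]
        self.gpr_ = best[2]
        self.X_train_ = X
        self.y_train_ = y
        self.extent_ = _margin_extent(X)
        return self

    def predict(self, X):
        """Posterior-mean pKi at coordinates X (m, 2)."""
        check_is_fitted(self, "gpr_")
        return self.gpr_.predict(np.asarray(X, dtype=float)) + self.offset_

    @property
    def noise_std_(self) -> float:
        """Fitted noise standard deviation (White level plus alpha), pKi units."""
        check_is_fitted(self, "gpr_")
        white = self.gpr_.kernel_.k2.noise_level
        return float(np.sqrt(white + self.alpha_))

    def to_raster(self, extent=None, width: int = IMAGE_WIDTH,
                  height: int = IMAGE_HEIGHT) -> PotencyRaster:
        """Rasterize the posterior mean on a regular pixel grid.

        Row 0 is the top of the image (largest y); column 0 the left
        (smallest x); pixel centers are evenly spaced over the extent.
        The default extent is the training bounding box plus a 5% margin
        per side.
        """
        check_is_fitted(self, "gpr_")
        if extent is None:
            extent = self.extent_
        xmin, xmax, ymin, ymax = extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"extent has non-positive area: {extent}")
        xs = xmin + (np.arange(width) + 0.5) * (xmax - xmin) / width
        ys = ymax - (np.arange(height) + 0.5) * (ymax - ymin) / height
        values = np.empty((height, width))
        # predict in row blocks to bound the kernel-matrix working memory
        block = 50
        for r0 in range(0, height, block):
            rows = ys[r0:r0 + block]
            gx, gy = np.meshgrid(xs, rows)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            values[r0:r0 + block] = self.predict(pts).reshape(len(rows), width)
        return PotencyRaster(values=values, extent=tuple(map(float, extent)))

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Write a portable JSON archive of the fitted surface."""
        check_is_fitted(self, "gpr_")
        payload = {
            "format": "alsim-surface",
            "version": 1,
            "params": self.get_params(),
            "alpha": self.alpha_,
            "offset": self.offset_,
            "theta": self.gpr_.kernel_.theta.tolist(),
            "extent": list(self.extent_),
            "train_coords": self.X_train_.tolist(),
            "train_potencies": self.y_train_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PotencySurfaceGPR":
        """Rebuild a fitted surface from a JSON archive.

        The stored hyperparameters are fixed (no re-optimization), so the
        reconstructed posterior is identical to the saved one.
        """
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "alsim-surface":
            raise ValueError(f"{path}: not a surface archive")
        model = cls(**payload["params"])
        X = np.asarray(payload["train_coords"], dtype=float)
        y = np.asarray(payload["train_potencies"], dtype=float)
        model.offset_ = float(payload["offset"])
        model.alpha_ = float(payload["alpha"])
        kernel = model._make_kernel(np.asarray(payload["theta"]))
        gpr = GaussianProcessRegressor(kernel=kernel, alpha=model.alpha_,
                                       optimizer=None, normalize_y=False)
        gpr.fit(X, y - model.offset_)
        model.gpr_ = gpr
        model.X_train_ = X
        model.y_train_ = y
        model.extent_ = tuple(payload["extent"])
        model.alpha_candidates_ = np.asarray([model.alpha_])
        model.log_marginal_likelihoods_ = np.asarray(
            [gpr.log_marginal_likelihood_value_])
        return model


def fit_surface(proj: np.ndarray, potencies, **params) -> PotencySurfaceGPR:
    """Fit a GP potency surface to projected coordinates and pKi values."""
    return PotencySurfaceGPR(**params).fit(proj, potencies)


def evaluate_surface(model: PotencySurfaceGPR, extent=None,
                     width: int = IMAGE_WIDTH, height: int = IMAGE_HEIGHT) -> PotencyRaster:
    """Rasterize a fitted surface (posterior-mean pKi per pixel)."""
    return model.to_raster(extent=extent, width=width, height=height)
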