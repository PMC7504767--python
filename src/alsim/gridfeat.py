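"""Grid featurization: 56x60 cell averaging and eight-category counts.

The intensity map is tiled by an evenly spaced 56x60 grid (3360 square
cells of 5x5 pixels); each cell takes the mean intensity of its 25
pixels and is assigned to one of eight threshold categories running from
the deepest valleys to the highest peaks.  The category counts, with no
locality information, are the activity landscape's feature vector.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import GRID_WIDTH, GRID_HEIGHT, IMAGE_WIDTH, IMAGE_HEIGHT, EPSILON
from .datatypes import CellDistribution

#: interior category boundaries; bins are lower-inclusive, the top bin
#: is closed at +1, so every intensity in [-1, 1] maps to one category
THRESHOLDS = np.array([-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75])
N_CATEGORIES = 8


def partition_cells(im: np.ndarray, grid_shape: tuple[int, int] = (GRID_HEIGHT, GRID_WIDTH)) -> np.ndarray:
    """Average the intensity map over disjoint grid-cell pixel blocks.

    Cell (r, c) is the mean of pixel rows [5r, 5r+5) and columns
    [5c, 5c+5) for the default 300x280 image and 60x56 grid.  Returns an
    array of shape ``grid_shape``.
    """
    im = np.asarray(im, dtype=float)
    rows, cols = grid_shape
    if im.ndim != 2:
        raise ValueError(f"expected a 2D intensity map, got shape {im.shape}")
    if grid_shape == (GRID_HEIGHT, GRID_WIDTH) and im.shape != (IMAGE_HEIGHT, IMAGE_WIDTH):
        raise ValueError(
            f"expected a {IMAGE_WIDTH}x{IMAGE_HEIGHT} intensity map, got "
            f"{im.shape[1]}x{im.shape[0]}")
    if im.shape[0] % rows or im.shape[1] % cols:
        raise ValueError(
            f"image shape {im.shape} does not tile into a {cols}x{rows} grid")
    bh, bw = im.shape[0] // rows, im.shape[1] // cols
    return im.reshape(rows, bh, cols, bw).mean(axis=(1, 3))


def categorize_cells(grid: np.ndarray, epsilon: float = EPSILON) -> CellDistribution:
    """Count grid cells per intensity category and smooth to probabilities.

    Categories (ascending): [-1, -0.75), [-0.75, -0.5), [-0.5, -0.25),
    [-0.25, 0), [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1].  A cell
    mean of exactly 0 falls in the first positive interval.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < -1) or np.any(grid > 1):
        raise ValueError("cell intensities must lie in [-1, 1]")
    cats = np.digitize(grid.ravel(), THRESHOLDS)  # 0..7, lower-inclusive
    counts = np.bincount(cats, minlength=N_CATEGORIES)
    return CellDistribution(counts=counts, epsilon=epsilon)


class GridFeaturizer(BaseEstimator, TransformerMixin):
    """Transform intensity maps into eight-category cell-count vectors.

    Parameters
    ----------
    grid_shape : (int, int), default=(60, 56)
        Grid rows and columns; the image must tile exactly.
    epsilon : float, default=0.5
        Additive smoothing per category for the probability vector.
    """

    def __init__(self, grid_shape: tuple[int, int] = (GRID_HEIGHT, GRID_WIDTH),
                 epsilon: float = EPSILON):
        self.grid_shape = grid_shape
        self.epsilon = epsilon

    def fit(self, X, y=None):
        return self  # stateless

    def transform(self, X) -> np.ndarray:
        """Featurize a stack of intensity maps (m, H, W) -> counts (m, 8)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.stack([
            self.featurize(im).counts for im in X
        ])
        return out[0] if single else out

    def featurize(self, im: np.ndarray) -> CellDistribution:
        """Full featurization of one intensity map to a CellDistribution."""
        return categorize_cells(partition_cells(im, self.grid_shape),
                                epsilon=self.epsilon)


# -- feature-vector serialization ---------------------------------------

def distribution_to_dict(dist: CellDistribution, dataset_id: str) -> dict:
    return {
        "dataset_id": dataset_id,
        "counts": dist.counts.tolist(),
        "probabilities": dist.probabilities.tolist(),
        "epsilon": dist.epsilon,
        "grid": f"{GRID_WIDTH}x{GRID_HEIGHT}",
        "image": f"{IMAGE_WIDTH}x{IMAGE_HEIGHT}",
    }


def write_features(dist: CellDistribution, dataset_id: str, path) -> None:
    """Write a feature vector as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(distribution_to_dict(dist, dataset_id), fh,
                  sort_keys=True, indent=2)
        fh.write("\n")


def read_features(path) -> tuple[str, CellDistribution]:
    """Read a feature-vector JSON back to (dataset_id, CellDistribution)."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("dataset_id", "counts", "epsilon"):
        if key not in payload:
            raise ValueError(f"{path}: missing feature-vector field {key!r}")
    return payload["dataset_id"], CellDistribution(
        counts=np.asarray(payload["counts"]), epsilon=payload["epsilon"])
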