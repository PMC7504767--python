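"""End-to-end activity-landscape construction and featurization."""

from __future__ import annotations

import os

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import CompoundSet, CellDistribution
from .chemspace import ChemicalSpaceEmbedding, distance_matrix
from .surface import PotencySurfaceGPR
from .heatmap import render_heatmap, rg_intensity, read_png
from .gridfeat import GridFeaturizer
from .config import EPSILON


class ActivityLandscape(BaseEstimator):
    """Full pipeline: compound set -> 3D activity landscape -> feature vector.

    Fitting runs the whole construction: pairwise Tanimoto distances,
    metric MDS to 2D, Gaussian-process potency surface, 280x300 heatmap
    rendering, RG-intensity extraction, and 56x60 grid featurization
    into the eight-category cell distribution.

    Parameters
    ----------
    random_state : int, default=0
        Seed for the MDS projection stage.
    epsilon : float, default=0.5
        Additive smoothing for the category probabilities.

    Attributes
    ----------
    embedding_ : ndarray (n, 2)
        2D chemical-space coordinates.
    surface_ : PotencySurfaceGPR
        Fitted potency surface.
    heatmap_ : ndarray (300, 280, 3), uint8
        Rendered RGB heatmap.
    intensity_ : ndarray (300, 280)
        Normalized RG intensity map in [-1, 1].
    distribution_ : CellDistribution
        The eight-category feature vector.
    """

    def __init__(self, random_state: int = 0, epsilon: float = EPSILON):
        self.random_state = random_state
        self.epsilon = epsilon

    def fit(self, X: CompoundSet, y=None):
        if not isinstance(X, CompoundSet):
            raise TypeError("ActivityLandscape.fit expects a CompoundSet")
        self.distance_matrix_ = distance_matrix(X)
        self.embedding_ = ChemicalSpaceEmbedding(
            random_state=self.random_state).fit_transform(self.distance_matrix_)
        self.surface_ = PotencySurfaceGPR().fit(self.embedding_, X.potencies)
        self.raster_ = self.surface_.to_raster()
        self.heatmap_ = render_heatmap(self.raster_)
        self.intensity_ = rg_intensity(self.heatmap_)
        self.distribution_ = GridFeaturizer(
            epsilon=self.epsilon).featurize(self.intensity_)
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted eight-category count vector."""
        return self.distribution_.counts


def feature_vector(source: CompoundSet | str | os.PathLike,
                   seed: int = 0, epsilon: float = EPSILON,
                   resize: bool = False) -> CellDistribution:
    """Featurize a compound set (full pipeline) or a pre-rendered heatmap PNG.

    Deterministic for a fixed ``seed``: the same input always yields the
    same :class:`CellDistribution`.
    """
    if isinstance(source, CompoundSet):
        return ActivityLandscape(random_state=seed,
                                 epsilon=epsilon).fit(source).distribution_
    img = read_png(source, resize=resize)
    return GridFeaturizer(epsilon=epsilon).featurize(rg_intensity(img))
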