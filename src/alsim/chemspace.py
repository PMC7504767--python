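"""Chemical reference space: fingerprints, Tanimoto distances, 2D embedding.

The chemical-space axes of an activity landscape come from metric
multidimensional scaling of the pairwise ECFP4 Tanimoto distance matrix:
compounds that share many circular substructures end up close together in
the 2D projection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import MDS
from sklearn.utils.validation import check_is_fitted

from .datatypes import CompoundSet

#: folded fingerprint length (bits) for ECFP4 generation
N_BITS = 2048


def compute_fingerprints(smiles_list: list[str], n_bits: int = N_BITS) -> list[set[int]]:
    """Compute folded ECFP4 fingerprints (Morgan, radius 2) from SMILES.

    Returns one set of on-bit indices per molecule.  Requires RDKit.

    Raises
    ------
    ValueError
        If a SMILES string cannot be parsed; the message names the
        offending record and its (1-based) position.
    ImportError
        If RDKit is not installed.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "computing fingerprints from SMILES requires RDKit "
            "(install the 'chem' extra); alternatively supply "
            "precomputed fingerprints"
        ) from exc

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fps: list[set[int]] = []
    for lineno, smi in enumerate(smiles_list, start=1):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at record {lineno}: {smi!r}")
        fps.append(set(gen.GetFingerprint(mol).GetOnBits()))
    return fps


def tanimoto_distance(fp_a: set[int], fp_b: set[int]) -> float:
    """Tanimoto distance 1 - |intersection|/|union| between two bit-index sets."""
    if not fp_a or not fp_b:
        raise ValueError("Tanimoto coefficient undefined for empty fingerprints")
    inter = len(fp_a & fp_b)
    union = len(fp_a) + len(fp_b) - inter
    return 1.0 - inter / union


def _fingerprints_to_matrix(fingerprints: list[set[int]]) -> np.ndarray:
    n_bits = max(max(fp) for fp in fingerprints) + 1
    mat = np.zeros((len(fingerprints), n_bits), dtype=np.float64)
    for i, fp in enumerate(fingerprints):
        mat[i, list(fp)] = 1.0
    return mat


def distance_matrix(compounds: CompoundSet | list[set[int]]) -> np.ndarray:
    """Pairwise Tanimoto distance matrix over a compound set.

    Accepts a :class:`CompoundSet` or a bare list of fingerprint sets.
    The result is symmetric with a zero diagonal and entries in [0, 1].
    Computed via the bit-count identity |a|b| = |a| + |b| - |a&b| on a
    dense 0/1 matrix, so the full matrix is a single matrix product.
    """
    fps = compounds.fingerprints if isinstance(compounds, CompoundSet) else compounds
    if any(not fp for fp in fps):
        raise ValueError("all fingerprints must be non-empty")
    mat = _fingerprints_to_matrix(fps)
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    dist = 1.0 - inter / union
    dist = np.asarray(dist, dtype=float)
    # exact symmetry / zero diagonal regardless of float roundoff
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


class ChemicalSpaceEmbedding(BaseEstimator, TransformerMixin):
    """2D chemical-space projection by metric MDS on a distance matrix.

    A single SMACOF run minimizes the metric stress (sum of squared
    differences between the input Tanimoto distances and the embedded
    Euclidean distances), initialized from the classical (Torgerson) MDS
    solution.  The classical initialization makes the embedding
    deterministic and, in practice, reaches lower stress than a handful
    of random restarts.

    Parameters
    ----------
    n_components : int, default=2
        Embedding dimensionality.
    max_iter : int, default=500
        SMACOF iteration cap.
    eps : float, default=1e-6
        Convergence tolerance on the stress decrement.
    random_state : int, default=0
        Seed for any stochastic fallback; the classical initialization
        itself is deterministic.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
        Projected coordinates, one row per compound.
    stress_ : float
        Final (raw) metric stress.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500,
                 eps: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit the embedding to a precomputed distance matrix X (n x n)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError(f"expected a square distance matrix, got shape {X.shape}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 items to embed")
        if not np.allclose(X, X.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        mds = MDS(
            n_components=self.n_components,
            metric="precomputed",
            metric_mds=True,
            n_init=1,
            init="classical_mds",
            max_iter=self.max_iter,
            eps=self.eps,
            random_state=self.random_state,
            normalized_stress=False,
        )
        self.embedding_ = mds.fit_transform(X)
        self.stress_ = float(mds.stress_)
        self.n_iter_ = int(mds.n_iter_)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X=None):
        """Return the fitted coordinates (out-of-sample mapping unsupported)."""
        check_is_fitted(self, "embedding_")
        return self.embedding_


def project_mds(dm: np.ndarray, seed: int = 0) -> np.ndarray:
    """Project a Tanimoto distance matrix to 2D coordinates via metric MDS."""
    return ChemicalSpaceEmbedding(random_state=seed).fit_transform(dm)
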