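"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CompoundSet:
    """A set of active compounds: ids, fingerprints and potencies.

    Parameters
    ----------
    ids : list of str
        Unique compound identifiers.
    fingerprints : list of set of int
        Binary fingerprints as sets of on-bit indices; every set non-empty.
    potencies : numpy.ndarray
        pKi values (negative decadic log of the inhibition constant),
        one per compound.
    smiles : list of str, optional
        SMILES strings, parallel to ``ids``.
    """

    ids: list[str]
    fingerprints: list[set[int]]
    potencies: np.ndarray
    smiles: list[str] | None = None

    def __post_init__(self) -> None:
        self.potencies = np.asarray(self.potencies, dtype=float)
        n = len(self.ids)
        if n < 2:
            raise ValueError(f"need at least 2 compounds, got {n}")
        if len(self.fingerprints) != n or len(self.potencies) != n:
            raise ValueError(
                "parallel lists differ in length: "
                f"{n} ids, {len(self.fingerprints)} fingerprints, "
                f"{len(self.potencies)} potencies"
            )
        if self.smiles is not None and len(self.smiles) != n:
            raise ValueError(f"{len(self.smiles)} smiles for {n} ids")
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate compound id: {dup!r}")
        for cid, fp in zip(self.ids, self.fingerprints):
            if not fp:
                raise ValueError(f"empty fingerprint for compound {cid!r}")
            if any(b < 0 for b in fp):
                raise ValueError(f"negative bit index in fingerprint of {cid!r}")
        if not np.all(np.isfinite(self.potencies)):
            bad = self.ids[int(np.flatnonzero(~np.isfinite(self.potencies))[0])]
            raise ValueError(f"non-finite potency for compound {bad!r}")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class PotencyRaster:
    """Per-pixel interpolated pKi values on a regular raster.

    ``values`` has shape (height, width); row 0 is the top of the image.
    ``extent`` is (xmin, xmax, ymin, ymax) in projection coordinates, with
    pixel centers evenly spaced over the extent.
    """

    values: np.ndarray
    extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster contains non-finite values")
        xmin, xmax, ymin, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"extent has non-positive area: {self.extent}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


class CellDistribution:
    """Distribution of grid cells over the eight intensity categories.

    Categories are ordered from the deepest valleys (strong green,
    intensity near -1) to the highest peaks (strong red, intensity near
    +1).  ``probabilities`` are additively smoothed relative frequencies,
    (count + eps) / (total + 8 * eps), so downstream Kullback-Leibler
    divergences stay finite when a category is empty.
    """

    def __init__(self, counts, epsilon: float = 0.5) -> None:
        counts = np.asarray(counts)
        if counts.shape != (8,):
            raise ValueError(f"expected 8 category counts, got shape {counts.shape}")
        if np.any(counts < 0) or not np.all(counts == counts.astype(int)):
            raise ValueError("counts must be nonnegative integers")
        if epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        self.counts = counts.astype(np.int64)
        self.epsilon = float(epsilon)
        total = self.counts.sum() + 8 * self.epsilon
        if total <= 0:
            raise ValueError("cannot normalize an all-zero, unsmoothed distribution")
        self.probabilities = (self.counts + self.epsilon) / total

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellDistribution):
            return NotImplemented
        return bool(
            np.array_equal(self.counts, other.counts)
            and self.epsilon == other.epsilon
        )

    def __repr__(self) -> str:
        return (
            f"CellDistribution(counts={self.counts.tolist()}, "
            f"epsilon={self.epsilon})"
        )


@dataclass(frozen=True)
class SimilarityResult:
    """Pairwise activity-landscape dissimilarity.

    ``re`` is the symmetric relative entropy (average of the two directed
    Kullback-Leibler divergences, in nats unless computed with base 2);
    ``cd`` is the cosine distance between the raw count vectors.
    """

    id_a: str
    id_b: str
    re: float
    cd: float
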