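"""Pairwise activity-landscape (dis)similarity measures.

Two cell distributions are compared by symmetric relative entropy — the
average of the two directed Kullback-Leibler divergences between their
smoothed probability vectors — and by cosine distance between the raw
count vectors.  Larger values of either measure indicate more dissimilar
landscape topologies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .datatypes import CellDistribution, SimilarityResult

_LN2 = np.log(2.0)


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1D probability vector")
    if np.any(p <= 0):
        raise ValueError(
            f"{name} contains non-positive entries; use smoothed "
            "probabilities (additive epsilon) so the divergence is finite")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {p.sum():.12f}, expected 1 within 1e-9")
    return p


def kl_divergence(p, q, base: str = "e") -> float:
    """Directed Kullback-Leibler divergence KLD(p || q) = sum p_i log(p_i/q_i).

    Natural log (nats) by default; ``base='2'`` for bits.  Both inputs
    must be strictly positive probability vectors of equal length.
    """
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    kld = float(np.sum(p * np.log(p / q)))
    if base == "2":
        kld /= _LN2
    elif base != "e":
        raise ValueError(f"base must be 'e' or '2', got {base!r}")
    return kld


def relative_entropy(p, q, base: str = "e") -> float:
    """Symmetric relative entropy: (KLD(p||q) + KLD(q||p)) / 2."""
    return 0.5 * (kl_divergence(p, q, base=base) + kl_divergence(q, p, base=base))


def cosine_distance(x, y) -> float:
    """Cosine distance 1 - x.y / (||x|| ||y||) between feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(x, y) / (nx * ny))


def compare_pair(a: CellDistribution, b: CellDistribution, id_a: str, id_b: str,
                 base: str = "e") -> SimilarityResult:
    """Compare one pair of cell distributions (RE on probabilities, CD on counts)."""
    return SimilarityResult(
        id_a=id_a, id_b=id_b,
        re=relative_entropy(a.probabilities, b.probabilities, base=base),
        cd=cosine_distance(a.counts, b.counts),
    )


def compare_all(features: list[tuple[str, CellDistribution]],
                base: str = "e") -> list[SimilarityResult]:
    """All-pairs comparison of labelled cell distributions.

    Returns one :class:`SimilarityResult` per unordered pair, sorted by
    (id_a, id_b) with id_a < id_b, so the output is independent of the
    input order.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 feature vectors to compare")
    ids = [fid for fid, _ in features]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate dataset id: {dup!r}")
    by_id = dict(features)
    results = []
    for id_a, id_b in combinations(sorted(ids), 2):
        results.append(compare_pair(by_id[id_a], by_id[id_b], id_a, id_b, base=base))
    return results
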