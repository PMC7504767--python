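"""Synthetic compound datasets and heatmap fixtures with controlled SAR.

Real activity classes are organized into analog series: clusters of
structurally similar compounds whose potencies are usually close, with
occasional activity cliffs (an analog far more or less potent than its
neighbors).  The generator emulates this: series centers scattered in
the unit square, compounds clustered around them, one shared base
potency per series, and — in a tunable ``ruggedness`` fraction of the
series — a co-located subgroup of analogs flipped to the opposite
potency extreme (an activity-cliff hot spot).  Synthetic fingerprints
combine per-series core bits with random-hyperplane position bits, so
Tanimoto distance grows with latent 2D distance both within and
between series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CompoundSet, PotencyRaster
from .heatmap import render_heatmap, PKI_GREEN, PKI_YELLOW, PKI_RED
from .config import IMAGE_WIDTH, IMAGE_HEIGHT

#: bit-space layout of the synthetic fingerprints
_N_POSITION_BITS = 256          # hyperplane-coded location bits, indices [0, 256)
_N_CORE_BITS = 96               # per-series core bits, indices [256, 2048)
_CORE_BIT_RANGE = (256, 2048)
#: within-series scatter of compounds around their center (unit-square units)
_SERIES_SCATTER = 0.08


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic activity class.

    Defaults mirror the scale of typical ChEMBL activity classes used
    for landscape analysis: several hundred compounds in a few dozen
    analog series spanning roughly six pKi log units.

    ``ruggedness`` is the fraction of series containing an activity
    cliff; ``noise_sd`` is per-compound Gaussian potency noise in pKi
    units (0.2 by default, the order of routine inter-assay scatter).
    """

    n_compounds: int = 700
    n_series: int = 20
    ruggedness: float = 0.0
    potency_range: tuple[float, float] = (4.0, 10.0)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_compounds < self.n_series:
            raise ValueError(
                f"need n_compounds >= n_series >= 1, got "
                f"{self.n_compounds} compounds, {self.n_series} series")
        if not 0.0 <= self.ruggedness <= 1.0:
            raise ValueError(f"ruggedness must be in [0, 1], got {self.ruggedness}")
        lo, hi = self.potency_range
        if not lo < hi:
            raise ValueError(f"potency range must increase, got {self.potency_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _position_fingerprint_bits(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random-hyperplane location code: bit b is on iff u_b . (x - t_b) > 0.

    The probability that a hyperplane with a random anchor point and
    direction separates two compounds grows with their distance, so the
    fraction of differing bits — and hence Tanimoto distance — increases
    with latent 2D distance.
    """
    t = rng.random((_N_POSITION_BITS, 2))
    theta = rng.uniform(0, 2 * np.pi, _N_POSITION_BITS)
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    # (n, bits): sign of the projection of (x - t_b) on u_b
    proj = (coords[:, None, :] - t[None, :, :]) * u[None, :, :]
    return proj.sum(axis=2) > 0


def generate_dataset(spec: SyntheticSpec) -> tuple[CompoundSet, np.ndarray]:
    """Generate a synthetic compound set plus its latent 2D coordinates.

    Returns ``(compound_set, latent_coords)`` where ``latent_coords``
    is the (n, 2) ground-truth chemical-space configuration the
    fingerprints encode.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_compounds, spec.n_series
    lo, hi = spec.potency_range

    centers = rng.random((k, 2))
    # balanced series assignment: sizes differ by at most one
    series = rng.permutation(np.arange(n) % k)
    coords = np.clip(
        centers[series] + rng.normal(0.0, _SERIES_SCATTER, (n, 2)), 0.0, 1.0)

    # series base potencies stratified over the range: real activity
    # classes span their whole potency window, so each dataset covers
    # low, intermediate and high levels rather than a random subset
    strata = lo + (hi - lo) * (rng.permutation(k) + 0.5) / k
    base = strata + rng.normal(0.0, 0.1 * (hi - lo) / k, k)
    potencies = base[series].copy()

    n_cliff_series = int(round(spec.ruggedness * k))
    cliff_series = rng.choice(k, size=n_cliff_series, replace=False)
    mid = 0.5 * (lo + hi)
    for s in cliff_series:
        members = np.flatnonzero(series == s)
        # an activity-cliff hot spot: a randomly picked analog and its
        # nearest in-series neighbors jump to the opposite potency
        # extreme; a coherent subgroup is needed for the discontinuity
        # to be structure rather than observation noise
        picked = rng.choice(members)
        d = np.linalg.norm(coords[members] - coords[picked], axis=1)
        group_size = max(2, int(round(0.15 * len(members))))
        group = members[np.argsort(d)[:group_size]]
        potencies[group] = hi if base[s] <= mid else lo
    potencies = potencies + rng.normal(0.0, spec.noise_sd, n)

    pos_bits = _position_fingerprint_bits(coords, rng)
    core_bits = [
        rng.choice(np.arange(*_CORE_BIT_RANGE), size=_N_CORE_BITS, replace=False)
        for _ in range(k)
    ]
    fingerprints = [
        set(np.flatnonzero(pos_bits[i]).tolist()) | set(core_bits[series[i]].tolist())
        for i in range(n)
    ]

    ids = [f"SYN{i:05d}" for i in range(n)]
    return CompoundSet(ids=ids, fingerprints=fingerprints,
                       potencies=potencies), coords


# -- image-level fixtures ------------------------------------------------

PATTERNS = ("constant", "smooth", "rugged", "split")


def generate_heatmap_fixture(pattern: str, seed: int = 0,
                             width: int = IMAGE_WIDTH,
                             height: int = IMAGE_HEIGHT) -> np.ndarray:
    """Render a controlled 280x300 heatmap for image-level tests.

    Patterns: ``constant`` (uniform red), ``smooth`` (one broad
    low-frequency potency wave), ``rugged`` (many narrow high-potency
    peaks on a low-potency background), ``split`` (left half red, right
    half green, aligned to the featurization grid).
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")

    if pattern == "constant":
        values = np.full((height, width), PKI_RED)
    elif pattern == "smooth":
        phase = rng.uniform(0, 2 * np.pi)
        angle = rng.uniform(0, 2 * np.pi)
        wave = np.sin(
            2 * np.pi * (np.cos(angle) * xx / width + np.sin(angle) * yy / height)
            + phase)
        mid, amp = PKI_YELLOW, 0.5 * (PKI_RED - PKI_GREEN)
        values = mid + amp * wave
    elif pattern == "rugged":
        values = np.full((height, width), PKI_GREEN, dtype=float)
        sigma = 6.0
        for _ in range(40):
            cx = rng.uniform(0, width)
            cy = rng.uniform(0, height)
            bump = (PKI_RED - PKI_GREEN + 1.0) * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
            values = np.maximum(values, PKI_GREEN + bump)
    elif pattern == "split":
        values = np.where(xx < width // 2, PKI_RED, PKI_GREEN)
    else:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")

    return render_heatmap(PotencyRaster(
        values=values, extent=(0.0, float(width), 0.0, float(height))))
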