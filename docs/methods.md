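# Methods

This note documents the models and procedures implemented in `alsim`,
the parameter choices that matter, what the synthetic data generator
does and does not emulate, and the package's known limitations.

## The activity-landscape model

An activity landscape (AL) couples two sources of information about a
compound dataset: pairwise structural similarity and potency. `alsim`
represents a dataset's AL as the composition

    fingerprints → Tanimoto distance matrix → 2D MDS projection
    → GP potency surface → RGB heatmap → RG intensity map
    → 56×60 cell grid → 8-category cell distribution,

and quantifies the (dis)similarity of two ALs by comparing their cell
distributions. The feature vector deliberately discards grid locality:
only the *distribution* of cell intensities is compared, which makes
the measure invariant to image orientation and to rigid motions of the
projection (MDS output is defined only up to rotation/reflection, so
this invariance is essential for the comparison to be well defined).
Spatial SAR information is not entirely lost, though: each pixel's
intensity comes from an interpolation over neighboring compounds, so
local potency contrast is encoded in the intensity values themselves.

## Chemical space

* **Fingerprints.** ECFP4-equivalent circular fingerprints (Morgan
  radius 2) folded to 2048 bits, computed with RDKit when SMILES are
  given. Precomputed fingerprints (sets of on-bit indices) may be
  supplied instead, which keeps the chemistry backend an optional
  dependency.
* **Distances.** Tanimoto distance `1 − |a∩b|/|a∪b|`; undefined (and
  rejected) for empty fingerprints. The full matrix is computed in
  double precision via the bit-count identity, then symmetrized and
  clipped to [0, 1] to remove float roundoff.
* **Projection.** Metric MDS (SMACOF stress majorization,
  scikit-learn). One run initialized from the classical (Torgerson)
  eigendecomposition solution, iteration cap 500, stress tolerance
  1e-6. The classical start is deterministic and, on Tanimoto matrices
  of clustered compound sets, consistently reaches stress at least as
  low as a handful of random restarts while being ~100× cheaper — with
  one seeded run this also makes the whole pipeline reproducible
  bit-for-bit. A `random_state` parameter is kept for interface
  stability. Exact coordinates are not comparable across MDS
  implementations; only stress-level equivalence is meaningful.

## Potency surface

* **Model.** Gaussian-process regression with kernel
  `Matern(ν = 1.5, ℓ ∈ [1e-2, 1e2]) + White(σ² ∈ [1e-5, 1])`, applied
  to mean-centered pKi values (the dataset mean is added back at
  prediction), which makes the zero-mean prior sensible for arbitrary
  potency ranges. ν = 1.5 gives a once-differentiable surface — smooth
  enough for coherent topography, rough enough to keep activity-cliff
  structure; the initial length scale is 1.0 in projection units.
* **Noise selection.** The diagonal regularization α is chosen from 10
  log-spaced candidates spanning [1e-7, 1e-1] by maximizing the log
  marginal likelihood, re-optimizing the kernel hyperparameters at each
  candidate (warm-started along the grid, which changes nothing about
  the selected optimum but avoids redundant optimizer work). α and the
  White term both add observation noise; fitting both lets the grid
  search pick a noise floor while the White term fine-tunes within it.
* **Rasterization.** The posterior mean is evaluated at the 280 × 300
  pixel centers of a regular grid spanning the training bounding box
  expanded by 5% per side (so no compound sits on the image border).
  Row 0 is the top of the image. The heatmap is thus a direct top-down
  rendering of the surface; no 3D plot, camera, or cropping is
  involved, which keeps the image pipeline deterministic.
* **Degenerate inputs.** Identical coordinates for all compounds are
  rejected; constant potencies produce a constant surface (the GP
  reverts to the subtracted mean).

## Color model and featurization

* **Gradient.** Green (0,255,0) at pKi ≤ 3.72, yellow (255,255,0) at
  5.75, red (255,0,0) at ≥ 8.75, linear in RGB between anchors, blue
  always 0, channels rounded half-up. The anchors are fixed,
  dataset-independent potency references, so heatmaps of different
  datasets share one intensity scale.
* **Intensity.** Per pixel `(R − G)/255 ∈ [−1, 1]`. White pixels have
  R = G and read as 0, the same as yellow — uncolored regions in
  externally rendered heatmaps therefore land in the intermediate
  categories without special-casing.
* **Grid.** 56 × 60 cells of exactly 5 × 5 pixels; cell value = mean of
  its 25 pixels; eight categories of width 0.25 from −1 to +1. Bins are
  lower-inclusive with the top bin closed at +1, so every value maps to
  exactly one category; a cell mean of exactly 0 goes to the first
  positive interval. (Any fixed boundary rule works; this one is
  documented and tested.)
* **Smoothing.** Probabilities are `(count + ε)/(3360 + 8ε)` with
  ε = 0.5 (Jeffreys-style additive smoothing), so Kullback–Leibler
  divergences stay finite when a category is empty in one distribution.
  Raw counts are retained alongside.

## Similarity measures

Symmetric relative entropy `RE = (KLD(P‖Q) + KLD(Q‖P))/2` on smoothed
probabilities, natural log by default (base 2 by flag; the base is
recorded in output metadata). Cosine distance `1 − cos∠(x, y)` on the
raw count vectors — cosine is scale-invariant, so counts and
frequencies are equivalent there and smoothing is unnecessary.

## Synthetic data generator

The generator emulates the structure of a ChEMBL-like activity class at
the scale of the datasets used for landscape analysis (defaults: 700
compounds in 20 analog series, pKi range 4–10, potency noise 0.2 pKi —
the order of routine inter-assay scatter):

* **Series.** Cluster centers uniform in the unit square; members
  scattered isotropically (σ = 0.08) around their center. Series base
  potencies are stratified evenly over the potency range (with jitter)
  rather than drawn i.i.d.: real heterogeneous activity classes span
  their whole potency window, and stratification makes the potency-level
  mix a property of the class design rather than of the seed.
* **Cliffs.** `ruggedness` is the fraction of series containing an
  activity-cliff hot spot: a randomly picked member *and its nearest
  in-series neighbors* (15% of the series, at least 2 compounds) jump
  to the opposite potency extreme. A coherent subgroup is required for
  the discontinuity to register as landscape structure — a single
  discordant compound is statistically indistinguishable from assay
  noise and is absorbed by the likelihood-optimized noise level, which
  is the correct GP behavior but leaves no topographical trace.
* **Fingerprints.** Per-series core bits (96 of 2048) shared by all
  members, plus 256 random-hyperplane position bits: bit *b* is on iff
  the compound lies on the positive side of a random line through a
  random anchor point. The probability that a line separates two
  compounds grows with their distance, so Tanimoto distance increases
  with latent 2D distance both within and between series — the only
  contract downstream stages rely on.

What the generator does **not** emulate: real substructure-driven
fingerprint correlations (bits are geometric, not chemical), potency
censoring and assay heterogeneity, series of strongly varying size, and
correlated multi-target activity. Passing pipeline tests on this data
therefore demonstrates that the method detects controlled topological
differences — not that it reproduces any particular real dataset's
numbers, which additionally depend on the exact projection produced by
the upstream rendering toolchain.

## Problem sizes used in tests

Unit tests run on small inputs (tens of compounds). The end-to-end
discrimination experiment uses the generator defaults — 700 compounds,
20 series — with 20 seeded replicates of four datasets each
(smooth reference, independent smooth, ruggedness 0.4, ruggedness 0.8),
chosen to mirror the scale of real activity classes while keeping a
full experiment within minutes on one CPU.

## Known limitations

* The MDS projection, and hence the heatmap, is not comparable
  coordinate-by-coordinate across implementations; only the
  orientation-invariant cell distribution is.
* A single global GP length scale must compromise between broad smooth
  regions and narrow cliffs; strongly multi-scale landscapes are
  smoothed conservatively (visible as high selected noise levels).
* RE is unbounded and ε-dependent for near-empty categories; CD is
  bounded in [0, 1] but insensitive to which categories differ.
* The potency gradient is clamped outside pKi 3.72–8.75; datasets lying
  mostly outside that window produce saturated, low-contrast heatmaps.
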