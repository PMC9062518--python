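# Methods

## Diversity labels

Each focal vegetation plot is labeled with three diversity values computed
over its *N* nearest neighboring plots (default *N* = 50; Euclidean distance
in projected meters, ties at equal distance broken by ascending plot id, the
focal plot never counted among its own neighbors):

- **alpha**: cardinality of the focal plot's species set. Species names are
  compared as exact normalized strings (trimmed, whitespace-collapsed,
  case-folded); taxonomic standardization is assumed to have happened
  upstream, e.g. against a checklist.
- **gamma**: cardinality of the union of species sets over the focal plot
  *and* its *N* neighbors. Including the focal plot is a deliberate choice:
  it guarantees `gamma ≥ alpha` and matches the picture of the neighborhood
  as the focal site plus its surroundings.
- **beta**: the multiple-site Sørensen dissimilarity
  `β_sor = (A + B) / (2 (Σᵢ Sᵢ − S_T) + A + B)`, with the pair terms taken
  between each neighbor and the focal plot, and the richness sum `Σᵢ Sᵢ`
  running over all *N* + 1 sites **including the focal plot**. Only this
  convention reduces to the classical pairwise Sørensen dissimilarity when
  *N* = 1, which anchors the index in its standard family. The denominator is
  zero exactly when every site is empty; that case raises an error.
- **radius**: distance from the focal plot to its *N*th neighbor — the
  smallest focal-centered circle encompassing the neighborhood. We adopt the
  focal-centered reading rather than the minimal enclosing circle of the
  neighbor point set; the two differ only in degenerate configurations, and
  the focal-centered value is what the prediction stage later substitutes to
  set the spatial scale of a map.

## Features

The full feature table has 27 columns: projected coordinates; two
sampling-effort measures (occurrence-record count and distinct-species count
within a 10 × 10 km window centered on the site, window membership half-open
on the max edges so grid seams never double-count); human footprint;
elevation; the 19 bioclimatic variables; plot size; neighborhood radius. Two
nested subsets (8 and 6 features, the latter dropping the coordinates) enter
model selection.

Occurrence records are cleaned before counting: non-fossil, human-observation
basis, no geospatial issue flags (the strict empty-flag rule — any flagged
record is dropped), binomial names only (exactly two whitespace-separated
tokens), and the name must appear in the accepted-name checklist (exact
normalized match; no fuzzy synonymy).

All spatial work happens in a Lambert cylindrical equal-area projection on a
sphere of authalic radius 6,371,007.2 m, standard parallel 30°S. The
spherical variant keeps closed-form forward/inverse formulas and an exactly
testable equal-area property; continent-scale distortion relative to an
ellipsoidal CEA is far below the 10 km analysis resolution. Raster values are
extracted by nearest-cell lookup (point-in-cell semantics appropriate for
~1 km cells), with nodata propagated as missing.

Features are min-max scaled to [0, 1]. The scaler is fitted on training rows
only and serialized with the model; prediction-grid features reuse the
training min/max, values outside the fitted range are *not* clipped, and
their count is reported — out-of-range cells are extrapolations and the count
makes that visible. Constant features scale to 0 by convention.

## Networks and training

One network per metric: fully connected, ReLU hidden layers with optional
dropout after each, one softplus output unit (`ln(1 + eˣ)`), guaranteeing
strictly positive diversity estimates with no upper bound. Labels are
rescaled to roughly [0, 1] before training (alpha × 1/100, gamma × 1/800,
beta unchanged) and the loss is the MAE of the scaled labels, minimized by
minibatch Adam with batch size 40.

Choices the training protocol leaves open, fixed here as package defaults:

- **Optimizer**: Adam, step size 1e-3, β = (0.9, 0.999), ε = 1e-8 — the
  de-facto standard for small MLP regression.
- **Initialization**: seeded He-uniform (fan-in) weights, zero biases.
- **Validation**: evaluated every epoch with dropout disabled (standard
  evaluation-mode semantics); the training loss recorded per epoch is the
  mean over that epoch's minibatches.
- **Determinism**: initialization, shuffling and dropout masks all derive
  from the config seed, so identical configs give bit-identical runs. The
  implementation is plain numpy with explicit backpropagation; the networks
  are small enough (hundreds of parameters) that a DL framework would add a
  dependency without adding capability, and explicit code keeps seeded
  reproducibility trivial.

Data are split 60/20/20 (train/validation/test); both holdout partitions get
`floor(0.2 n)` instances. Model selection trains every combination of
{27, 8, 6 features} × {(30), (30, 5), (30, 15, 5), (30, 20, 10, 5)} ×
{0, 0.1, 0.3 dropout} — 36 configurations — and ranks by test-set MAPE
(`100 · mean(|pred − truth| / truth)`; zero-truth instances, possible for
beta = 0 sites, are excluded and counted, since the ratio is undefined
there). The stopping epoch is the best validation epoch rounded to the
nearest multiple of 50 (round-half-up, floored at 50, validation ties going
to the earlier epoch). The winning configuration is retrained on *all* data
for exactly that many epochs as an ensemble of 50 members seeded
`base_seed + index`.

## Prediction

Maps are produced on a regular grid (default 10 × 10 km cell size; cells
whose centers fall outside the extent or off an optional land mask are
dropped). Grid features are built exactly as training features, with the
plot-size column fixed (default 500 m²) and the radius column fixed (default
5 km, matching the cell scale); both should stay inside the training range —
a warning fires otherwise, and alpha predictions are then read as "expected
species in a plot of the chosen size", gamma as richness at the chosen
neighborhood scale.

Per cell: ensemble mean, standard deviation in population form (divisor *n*
— the ensemble is the complete population of trained members, not a sample),
and CV = sd/mean. CV at an exactly-zero mean is set to 0 and counted
(softplus makes this practically impossible; the guard is for malformed
inputs). Cells with CV strictly greater than the median CV over all cells of
the run are masked as high-uncertainty; ties at the median stay unmasked, so
the retained cells are exactly those with CV smaller than or equal to the
median. Region summaries (over a category raster, e.g. biomes) report cell
counts and mean/quantiles over unmasked cells only; fully masked regions are
reported with `n_unmasked = 0` and NaN statistics rather than dropped.

## Synthetic landscapes

The generator emulates the statistical shape of the real inputs, not their
content:

- **Environmental layers** are sums of 5 low-frequency random sinusoids,
  rescaled to plausible per-variable ranges — smooth and spatially
  autocorrelated like interpolated climate surfaces, but with none of their
  cross-correlation structure.
- **Plots** are clustered around random centers (Gaussian scatter, sd = 2% of
  the extent) with log-uniform areas in [50, 10,000] m², matching the range
  of real plot databases.
- **Expected richness** is `μ = 15 · exp(g (e − 0.5)) · (area/500)^0.25`,
  where `e ∈ [0, 1]` is the designated driver layer (BIO1) at the plot and
  `g` the gradient strength (default 1.5). The area exponent 0.25 is a
  typical species–area slope; 500 m² is the reference plot size. Realized
  richness is Poisson(μ) floored at 1.
- **Composition** is drawn from a pool of 400 binomial-named species, each
  with a random range center; availability decays exponentially with
  distance (10 km scale, plus a 0.02 baseline so the pool is never locally
  exhausted), sampled without replacement via the Gumbel-top-k trick. This
  induces distance-decaying similarity — realistic, nonzero, non-unit beta.
- **Occurrences** are placed with intensity ∝ exp(bias · human-footprint),
  giving the spatially uneven sampling density the effort features are meant
  to correct for; 12% of rows are contaminated with exactly one cleaning-rule
  violation each, and the checklist carries 10% unmatched noise names, so the
  filter has real work to do.

What a green test on this world establishes: the pipeline's arithmetic is
correct and the networks can recover a known environment→diversity signal at
desk scale. What it does not establish: performance on real data — real
landscapes have correlated predictors, observer and detection biases,
taxonomic noise, and spatial sampling structure far richer than a clustered
Poisson process, so error levels measured here do not transfer.

## Numerical notes and limitations

- Neighbor search uses a KD-tree over all plots; within each returned
  neighbor set, equal-distance ties are re-sorted by plot id for determinism.
  Ties straddling the *k*th-neighbor cutoff are resolved by the tree and are
  measure-zero for continuous coordinates.
- Softplus is evaluated as `logaddexp(0, x)` and its derivative via a
  numerically stable sigmoid; MAE's subgradient at zero residual is taken
  as 0.
- Label rescaling round-trips to machine precision, not bit-exactly
  (multiplication by 1/100 is not exactly invertible in binary floating
  point).
- Rasters are single-band GeoTIFF (pixel-scale/tiepoint tags, square cells)
  or ESRI ASCII grids; reprojection of arbitrary input rasters into the CEA
  grid is the caller's concern.
- Region input is a category raster; polygon regions must be rasterized
  upstream.
- The package trains on one CPU; the reference-scale run (7,896 sites ×
  36 configs × ~2,000 epochs) is feasible but slow — the tests and the
  acceptance script use scaled-down grids (hundreds of plots, ≤ 300 epochs,
  ensembles of 5) that preserve every contract while finishing in seconds.
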