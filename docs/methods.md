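# Methods

## Model

A landscape mosaic is a categorical raster: `N` cells, `m` classes with
sizes `N_i`, and — under a chosen neighbor rule — patches ("continuous
spaces") of contiguous same-class cells with sizes `r_ij`. The absolute
extended Boltzmann entropy discounts the repetitive information carried by
contiguity:

    S = ln N! − Σ_i ln N_i! − Σ_ij ln r_ij!     (k_B = 1, nats)

`S` can be negative: a single class forming a single patch gives
`S = ln N! − ln N! − ln N! = −ln N!`. The value is reported as defined,
without clamping; it is a log-ratio of microstate counts, not a probability.

Each log-factorial sum is expanded through the identity
`Σ ln s! = Σ_k a_k ln k` with `a_k = #{sizes ≥ k}` — a histogram over the
bins `ln 1, ln 2, …` ("extended logarithmic distribution"). Because the
bins are ordered on a line and the reference is a Dirac mass at
`ln 1 = 0`, the 1-D Wasserstein cost degenerates to mass × distance summed,
`(1/M) Σ_k a_k ln k` with `M = Σ sizes`; no optimal-transport solver is
needed, and the histogram route equals `Σ ln s! / M` in closed form. Both
routes are implemented and tested against each other and against exact
big-integer factorials on small inputs.

The normalizing maximum cost is the transport from the Dirac reference to
the most uniform state distribution — equal mass `1/N` on each of the `N`
bins — costing `ln(N!)/N`. This is the only normalization under which both
terms lie in `[0, 1]` with the closed forms

    Wc = Σ_i ln N_i! / ln N!,   Ws = Σ_ij ln r_ij! / ln N!,

and the relative entropy is `Wdist = (1 − Wc)(1 − Ws)`: 0 iff one class
forms one patch, 1 iff every cell is its own class. Because 8-neighbor
adjacency can only merge patches relative to 4-neighbor adjacency, and
`ln a! + ln b! ≤ ln (a+b)!`, always `Ws(8) ≥ Ws(4)` and
`Wdist(8) ≤ Wdist(4)`.

## Parameters

- **connectivity** (4 or 8): the neighbor rule for patch delineation;
  4 (edge-sharing) is the default and the traditional choice, 8 adds
  diagonals.
- **nodata label** (optional): masked cells are excluded from `N`, from all
  class counts, and patches never span them. The entropy definition has no
  native missing-data concept; exclusion is the least-surprising extension.
- **quantization** of continuous surfaces (e.g. DEMs): equal-interval with
  a user-set bin count is the default; explicit edges and rank-based
  quantile modes are available. Interior bin edges are half-open `[lo, hi)`
  with the last bin closed. There is no canonical binning for elevations;
  the choice is exposed as a flag because it changes `m` and hence every
  result.

## Numerical choices

- Log-factorials via `scipy.special.gammaln(n+1)` everywhere; exact to
  double precision and immune to the overflow that direct factorials hit
  near `n = 171`. Exact big-integer factorials appear only in test oracles.
- `normalized_cost` clamps ~1 ulp of division roundoff into `[0, 1]`.
- `N = 1` is rejected for the relative entropy (the normalizer
  `ln(1!)/1 = 0` makes it undefined) rather than assigned a value.
- Quantile/rank classification breaks ties by row-major scan order via a
  stable sort, making classification deterministic; class `c` receives its
  rounded cumulative share of cells, so each count is within one cell of
  `p_c · N`.
- Connected-component labeling uses `scipy.ndimage.label` with a
  cross-shaped (4) or full 3×3 (8) structuring element, validated against a
  brute-force flood-fill oracle in the tests.

## Synthetic landscapes

`generate_fractal_surface` synthesizes fractional-Brownian surfaces
spectrally: white complex Gaussian noise shaped by the amplitude
`|f|^−(H+1)` (the 2-D fBm power spectrum `f^−(2H+2)`), inverse-FFT'd and
standardized. The Hurst exponent `H ∈ (0, 1)` controls autocorrelation:
the empirical variogram grows as `lag^(2H)` over small lags, the tested
contract. Discrete spectral synthesis is periodic and truncates the
spectrum at the Nyquist frequency, so the realized variogram slope is
biased upward at low `H`; the trend in `H` is faithful, which is what the
downstream ordering checks rely on. Quantile classification then fixes the
class proportions exactly (to within one cell), emulating neutral-landscape
generators that hold composition constant while varying aggregation.

`randomize_rows` permutes the cells of the first `k` rows jointly (not
within each row), preserving the whole-raster composition exactly while
destroying spatial structure in the band — the design used to grade image
dissimilarity. Every generator takes one explicit seed and keeps no global
RNG state, so all outputs are bit-reproducible.

What the generators do *not* emulate: real landscapes' anisotropy,
landform-driven class adjacency rules, multi-scale patchiness beyond a
single power law, or spatially structured missing data. Passing trend tests
on these surfaces shows the entropy orders synthetic aggregation levels
correctly; it does not calibrate absolute values for any particular real
map.

## Problem sizes and test design

The ordering checks use 128×128 mosaics with six equal classes (20
replicates per Hurst level) for the aggregation trend, and a 256×256
eight-class seed mosaic (10 replicates) for the row-randomization trend —
sizes at which the patch-size distributions are stable enough that the
trends hold in every or nearly every replicate while the full suite runs in
seconds. Exact-value tests use 2×2–8×8 fixtures where factorials can be
enumerated. Batch determinism is asserted at the byte level on CSV output
across worker counts; parallelism is one process per input file, so
scheduling cannot reorder results.

## Limitations

- `Wc` and `Ws` share one normalizer `ln N!`, so values are comparable only
  across mosaics of equal `N`.
- Patches are defined strictly by the raster lattice; no geodesic or
  distance-weighted adjacency.
- The CSV stores six significant digits; downstream comparisons tighter
  than 1e−6 should use the Python API.
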