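"""Synthetic landscape mosaics with controlled composition and structure.

Two families of synthetic data are provided, matching the experimental
designs the entropy is meant to discriminate:

* neutral landscapes: fractional-Brownian surfaces with a Hurst exponent H
  in (0, 1) controlling spatial autocorrelation (low H = rough/disordered,
  high H = smooth/aggregated), quantile-classified into a fixed number of
  classes with fixed proportions; and
* row-randomized mosaics: a seed raster whose first k rows are shuffled,
  degrading spatial structure while preserving composition exactly.

Plus small deterministic fixtures (checkerboard, stripes, uniform,
all-distinct) for exact-value tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import CategoricalRaster, QuantizationRule, quantize

__all__ = [
    "NeutralLandscapeConfig",
    "generate_fractal_surface",
    "classify_by_quantile",
    "generate_neutral_landscape",
    "randomize_rows",
    "make_fixture",
]


@dataclass(frozen=True)
class NeutralLandscapeConfig:
    """Parameters of a neutral landscape: size, Hurst exponent H, class
    count and per-class proportions, and the RNG seed."""

    rows: int
    cols: int
    hurst: float
    n_classes: int
    proportions: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("Hurst exponent must lie in (0, 1)")
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != self.n_classes:
            raise ValueError("n_classes must equal the number of proportions")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")

    @classmethod
    def equal_proportions(
        cls, rows: int, cols: int, hurst: float, n_classes: int, seed: int
    ) -> "NeutralLandscapeConfig":
        return cls(rows, cols, hurst, n_classes, (1.0 / n_classes,) * n_classes, seed)


def generate_fractal_surface(rows: int, cols: int, hurst: float, seed: int) -> np.ndarray:
    """Fractional-Brownian surface by spectral synthesis.

    White complex Gaussian noise is shaped in the frequency domain with
    amplitude |f|^-(H+1) — the 2-D power spectrum f^-(2H+2) of fractional
    Brownian motion — and inverse-transformed.  The empirical variogram of
    the result grows as lag^(2H) over small lags; higher H gives a smoother,
    more autocorrelated surface.  The output is standardized to zero mean
    and unit variance, which changes no rank-based classification.
    """
    if rows < 2 or cols < 2:
        raise ValueError("surface must be at least 2x2")
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    freq = np.hypot(fy, fx)
    freq[0, 0] = np.inf  # zero-mean: kill the DC component
    amplitude = freq ** -(hurst + 1.0)
    noise = rng.standard_normal((rows, cols)) + 1j * rng.standard_normal((rows, cols))
    surface = np.fft.ifft2(amplitude * noise).real
    surface -= surface.mean()
    std = surface.std()
    if std > 0:
        surface /= std
    return surface


def classify_by_quantile(surface: np.ndarray, proportions: tuple[float, ...]) -> CategoricalRaster:
    """Rank-classify a surface so class c receives its rounded cumulative
    share of cells (ties broken by row-major scan order)."""
    rule = QuantizationRule(mode="quantile", proportions=tuple(proportions))
    return quantize(surface, rule)


def generate_neutral_landscape(config: NeutralLandscapeConfig) -> CategoricalRaster:
    """Fractal surface + quantile classification in one step."""
    surface = generate_fractal_surface(config.rows, config.cols, config.hurst, config.seed)
    return classify_by_quantile(surface, config.proportions)


def randomize_rows(raster: CategoricalRaster, k_rows: int, seed: int) -> CategoricalRaster:
    """Permute the cells of the first ``k_rows`` rows uniformly at random.

    Cells are shuffled jointly across those rows (not within each row), so
    the class composition of the whole raster is preserved exactly while
    spatial structure in the randomized band is destroyed.  Nodata cells in
    the band are shuffled along with their labels.
    """
    n_rows = raster.shape[0]
    if not 0 <= k_rows <= n_rows:
        raise ValueError(f"k_rows must be in [0, {n_rows}], got {k_rows}")
    if k_rows == 0:
        return raster
    rng = np.random.default_rng(seed)
    values = raster.values.copy()
    mask = raster.nodata_mask.copy()
    band = values[:k_rows].ravel()
    band_mask = mask[:k_rows].ravel()
    perm = rng.permutation(band.size)
    values[:k_rows] = band[perm].reshape(k_rows, -1)
    mask[:k_rows] = band_mask[perm].reshape(k_rows, -1)
    return CategoricalRaster(values, mask)


def make_fixture(name: str, rows: int, cols: int) -> CategoricalRaster:
    """Deterministic test mosaics.

    ``checkerboard``: classes 0/1 by cell parity; ``stripes``: classes 0/1
    alternating by row; ``uniform``: one class; ``all_distinct``: every cell
    its own class.
    """
    if rows < 1 or cols < 1:
        raise ValueError("fixture must have rows, cols >= 1")
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    if name == "checkerboard":
        values = (r + c) % 2
    elif name == "stripes":
        values = np.broadcast_to(r % 2, (rows, cols)).copy()
    elif name == "uniform":
        values = np.zeros((rows, cols), dtype=np.int64)
    elif name == "all_distinct":
        values = np.arange(rows * cols).reshape(rows, cols)
    else:
        raise ValueError(f"unknown fixture name: {name!r}")
    return CategoricalRaster(values.astype(np.int64))
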