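"""Reading, validating, quantizing and writing landscape mosaics.

A landscape mosaic is a categorical raster: a 2-D grid in which every cell
carries one integer class label.  This module handles the I/O side of the
package — whitespace-delimited text grids, grayscale images whose gray
levels act as classes, quantization of continuous surfaces (e.g. digital
elevation models) into classes, and the CSV result table.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .entropy_core import EntropyResult

__all__ = [
    "CategoricalRaster",
    "QuantizationRule",
    "RasterFormatError",
    "read_text_grid",
    "write_text_grid",
    "read_image_grayscale",
    "quantize",
    "write_results",
]


class RasterFormatError(ValueError):
    """Raised for malformed raster inputs (ragged rows, bad tokens, empty files)."""


@dataclass(frozen=True)
class CategoricalRaster:
    """A categorical raster ("landscape mosaic") with an optional nodata mask.

    Parameters
    ----------
    values
        R×C integer array of class labels.  Entries under the nodata mask
        are ignored by every downstream computation.
    nodata_mask
        R×C boolean array; ``True`` marks cells excluded from analysis.
        Defaults to all-valid.
    """

    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.floating) and np.all(
                np.isfinite(values) & (values == np.round(values))
            ):
                values = values.astype(np.int64)
            else:
                raise ValueError("class labels must be finite integers")
        values = np.ascontiguousarray(values, dtype=np.int64)

        mask = self.nodata_mask
        if mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        else:
            mask = np.ascontiguousarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError("nodata_mask shape must match values shape")
        if mask.all():
            raise ValueError("raster has no valid (non-nodata) cells")
        values.flags.writeable = False
        mask.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        """Number of non-nodata cells (N in the entropy formulas)."""
        return int((~self.nodata_mask).sum())

    def valid_values(self) -> np.ndarray:
        """Flat array of class labels at valid cells, row-major order."""
        return self.values[~self.nodata_mask]


QuantizationMode = Literal["distinct-values", "equal-interval", "explicit-edges", "quantile"]


@dataclass(frozen=True)
class QuantizationRule:
    """How to turn a continuous surface into classes.

    Modes
    -----
    ``distinct-values``
        Every distinct value becomes its own class (for already-categorical
        surfaces stored as reals).
    ``equal-interval``
        ``n_bins`` equal-width bins over the observed range; half-open
        ``[lo, hi)`` intervals, last bin closed.
    ``explicit-edges``
        User-supplied strictly increasing bin edges, same interval rule;
        values outside the edges clip into the end bins.
    ``quantile``
        Rank-based assignment so class c receives its rounded cumulative
        share of cells; either ``n_bins`` equal shares or explicit
        ``proportions``.
    """

    mode: QuantizationMode
    n_bins: int | None = None
    edges: tuple[float, ...] | None = None
    proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("distinct-values", "equal-interval", "explicit-edges", "quantile"):
            raise ValueError(f"unknown quantization mode: {self.mode!r}")
        if self.mode == "explicit-edges":
            if self.edges is None or len(self.edges) < 2:
                raise ValueError("explicit-edges mode requires at least 2 edges")
            e = np.asarray(self.edges, dtype=float)
            if not np.all(np.diff(e) > 0):
                raise ValueError("explicit edges must be strictly increasing")
        elif self.mode in ("equal-interval", "quantile"):
            if self.mode == "quantile" and self.proportions is not None:
                p = np.asarray(self.proportions, dtype=float)
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError("proportions must be nonnegative and sum to 1")
            elif self.n_bins is None or self.n_bins < 1:
                raise ValueError(f"{self.mode} mode requires n_bins >= 1")


def read_text_grid(path: str | os.PathLike, nodata: int | None = None) -> CategoricalRaster:
    """Read a whitespace-delimited integer grid; row 0 of the file is row 0.

    Parameters
    ----------
    path
        Text file of newline-separated rows of whitespace-separated integers.
    nodata
        Optional label whose cells are masked out and excluded from N.
    """
    rows: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                rows.append([int(tok) for tok in tokens])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: non-integer token on line {lineno}"
                ) from exc
            if len(rows[-1]) != len(rows[0]):
                raise RasterFormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(rows[-1])} columns, expected {len(rows[0])})"
                )
    if not rows:
        raise RasterFormatError(f"{path}: empty grid file")
    values = np.array(rows, dtype=np.int64)
    mask = np.zeros(values.shape, dtype=bool) if nodata is None else values == nodata
    if mask.all():
        raise RasterFormatError(f"{path}: every cell is nodata")
    return CategoricalRaster(values, mask)


def write_text_grid(
    raster: CategoricalRaster, path: str | os.PathLike, nodata: int | None = None
) -> None:
    """Write a raster as a whitespace-delimited text grid (round-trips with
    :func:`read_text_grid`).  Nodata cells require an explicit ``nodata`` label."""
    values = raster.values
    if raster.nodata_mask.any():
        if nodata is None:
            raise ValueError("raster has nodata cells; supply a nodata label to write them")
        values = np.where(raster.nodata_mask, nodata, values)
    with open(path, "w", encoding="utf-8") as fh:
        for row in values:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_image_grayscale(path: str | os.PathLike) -> CategoricalRaster:
    """Read an image as a mosaic: each distinct 8-bit gray level is one class.

    Color images are converted to luminance ("L" mode, ITU-R 601-2 weights)
    before binning to 8 bits, so an RGB input yields at most 256 classes.
    """
    try:
        with Image.open(path) as img:
            gray = img.convert("L")
            values = np.asarray(gray, dtype=np.int64)
    except (UnidentifiedImageError, OSError) as exc:
        raise RasterFormatError(f"{path}: cannot decode image") from exc
    return CategoricalRaster(values)


def quantize(surface: np.ndarray, rule: QuantizationRule) -> CategoricalRaster:
    """Quantize a continuous surface into a categorical raster.

    NaN cells become nodata.  Labels are bin indices ``0..n_bins-1``.
    Interior bin edges are half-open ``[lo, hi)`` (a value equal to an
    interior edge goes to the upper bin); the last bin is closed.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != 2 or surface.size == 0:
        raise ValueError("surface must be a non-empty 2-D array")
    nodata = np.isnan(surface)
    if nodata.all():
        raise RasterFormatError("surface has no valid cells")
    valid = surface[~nodata]
    if not np.all(np.isfinite(valid)):
        raise ValueError("surface must be finite where not nodata")

    labels = np.zeros(surface.shape, dtype=np.int64)
    if rule.mode == "distinct-values":
        uniq, inverse = np.unique(valid, return_inverse=True)
        labels[~nodata] = inverse
    elif rule.mode in ("equal-interval", "explicit-edges"):
        if rule.mode == "equal-interval":
            lo, hi = float(valid.min()), float(valid.max())
            if lo == hi:  # degenerate flat surface: one class
                edges = np.array([lo, lo + 1.0])
            else:
                edges = np.linspace(lo, hi, rule.n_bins + 1)  # type: ignore[operator]
        else:
            edges = np.asarray(rule.edges, dtype=float)
        # digitize against interior edges: value == edge goes to the upper bin
        idx = np.digitize(valid, edges[1:-1], right=False)
        labels[~nodata] = idx
    elif rule.mode == "quantile":
        if rule.proportions is not None:
            props = np.asarray(rule.proportions, dtype=float)
        else:
            props = np.full(rule.n_bins, 1.0 / rule.n_bins)  # type: ignore[arg-type]
        labels[~nodata] = _rank_classify(valid, props)
    return CategoricalRaster(labels, nodata)


def _rank_classify(values: np.ndarray, proportions: np.ndarray) -> np.ndarray:
    """Assign classes by rank so class c gets its rounded cumulative share.

    Ties are broken by scan (row-major) order via a stable sort, so the
    assignment is deterministic.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    cuts = np.rint(np.cumsum(proportions) * n).astype(np.int64)
    cuts[-1] = n  # guard against rounding drift in the final cumulative share
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for c, stop in enumerate(cuts):
        labels[order[start:stop]] = c
        start = stop
    return labels


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_results(results: Iterable["EntropyResult"], path: str | os.PathLike | io.TextIOBase) -> None:
    """Write entropy results as CSV, one row per (input, connectivity).

    Columns: ``file,n,m,connectivity,wc,ws,wdist,s_absolute``; floats at six
    significant digits; row order equals input order (deterministic bytes).
    """
    own = isinstance(path, (str, os.PathLike))
    fh = open(path, "w", newline="", encoding="utf-8") if own else path
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["file", "n", "m", "connectivity", "wc", "ws", "wdist", "s_absolute"])
        for res in results:
            writer.writerow(
                [
                    res.source or "",
                    res.n,
                    res.m,
                    res.connectivity,
                    _format_float(res.wc),
                    _format_float(res.ws),
                    _format_float(res.wdist),
                    _format_float(res.s_absolute),
                ]
            )
    finally:
        if own:
            fh.close()
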