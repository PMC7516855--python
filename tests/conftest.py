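import math

import numpy as np
import pytest

from mosaicentropy import CategoricalRaster


def exact_log_factorial(n: int) -> float:
    """Independent oracle: log of the exact big-integer factorial."""
    return math.log(math.factorial(n)) if n > 1 else 0.0


def exact_normalized_cost(sizes, n_total: int) -> float:
    """Closed-form oracle: sum ln(s!)/ln(N!) via exact factorials."""
    return sum(exact_log_factorial(s) for s in sizes) / exact_log_factorial(n_total)


def flood_fill_components(values: np.ndarray, connectivity: int) -> dict[int, list[int]]:
    """Brute-force component sizes per class via explicit flood fill.

    Independent of scipy.ndimage; used as the labeling oracle on tiny grids.
    """
    rows, cols = values.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(values, dtype=bool)
    out: dict[int, list[int]] = {}
    for r in range(rows):
        for c in range(cols):
            if seen[r, c]:
                continue
            label = int(values[r, c])
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr, dc in offsets:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and not seen[nr, nc] and values[nr, nc] == label:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            out.setdefault(label, []).append(size)
    return out


def random_raster(rng: np.random.Generator, max_side: int = 12, max_classes: int = 6) -> CategoricalRaster:
    rows = int(rng.integers(1, max_side + 1))
    cols = int(rng.integers(1, max_side + 1))
    if rows * cols == 1:
        cols = 2
    m = int(rng.integers(1, max_classes + 1))
    return CategoricalRaster(rng.integers(0, m, size=(rows, cols)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
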