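"""Unit and property tests for the entropy computations.

Expected values come from two independent oracles: exact big-integer
factorials (conftest.exact_normalized_cost) and a brute-force flood-fill
component labeler (conftest.flood_fill_components).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicentropy import (
    CategoricalRaster,
    absolute_entropy,
    class_composition,
    component_inventory,
    dirac_transport_cost,
    log_term_histogram,
    make_fixture,
    max_transport_cost,
    normalized_cost,
    wdist,
)

from conftest import exact_log_factorial, exact_normalized_cost, flood_fill_components, random_raster


class TestClassComposition:
    def test_counts_and_total(self):
        comp = class_composition(CategoricalRaster(np.array([[1, 1], [2, 2]])))
        assert comp.counts == {1: 2, 2: 2}
        assert comp.m == 2 and comp.n_total == 4

    def test_checkerboard_counts(self):
        comp = class_composition(make_fixture("checkerboard", 4, 4))
        assert comp.counts == {0: 8, 1: 8}

    def test_nodata_excluded(self):
        raster = CategoricalRaster(np.array([[1, 9], [1, 2]]), np.array([[False, True], [False, False]]))
        comp = class_composition(raster)
        assert comp.counts == {1: 2, 2: 1} and comp.n_total == 3


class TestComponentInventory:
    @pytest.mark.parametrize("conn,expected", [
        (4, {1: [2], 2: [2]}),
        (8, {1: [2], 2: [2]}),
    ])
    def test_two_stripes(self, conn, expected):
        inv = component_inventory(CategoricalRaster(np.array([[1, 1], [2, 2]])), conn)
        assert {k: sorted(v) for k, v in inv.sizes.items()} == expected

    @pytest.mark.parametrize("conn,n_components,sizes", [
        (4, 16, {1}),   # diagonal cells are not neighbors: all singletons
        (8, 2, {8}),    # diagonal adjacency joins each color into one patch
    ])
    def test_checkerboard_connectivity(self, conn, n_components, sizes):
        inv = component_inventory(make_fixture("checkerboard", 4, 4), conn)
        flat = inv.all_sizes()
        assert len(flat) == n_components
        assert set(flat) == sizes

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(40):
            raster = random_raster(rng, max_side=8, max_classes=4)
            for conn in (4, 8):
                inv = component_inventory(raster, conn)
                oracle = flood_fill_components(np.asarray(raster.values), conn)
                assert {k: sorted(v) for k, v in inv.sizes.items()} == {
                    k: sorted(v) for k, v in oracle.items()
                }

    def test_components_do_not_span_nodata(self):
        values = np.array([[1, 1, 1]])
        mask = np.array([[False, True, False]])
        inv = component_inventory(CategoricalRaster(values, mask), 4)
        assert sorted(inv.sizes[1]) == [1, 1]

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            component_inventory(make_fixture("uniform", 2, 2), 6)


class TestLogTermHistogram:
    @pytest.mark.parametrize("sizes,expected,total", [
        ([3, 2], {1: 2, 2: 2, 3: 1}, 5),
        ([1, 1, 1], {1: 3}, 3),
        ([4], {1: 1, 2: 1, 3: 1, 4: 1}, 4),
    ])
    def test_expansion_counts(self, sizes, expected, total):
        hist = log_term_histogram(sizes)
        assert hist.mass == expected
        assert hist.total_mass == total

    def test_mass_nonincreasing(self, rng):
        sizes = rng.integers(1, 30, size=25)
        hist = log_term_histogram(sizes)
        masses = [hist.mass[k] for k in sorted(hist.mass)]
        assert all(a >= b for a, b in zip(masses, masses[1:]))
        assert hist.total_mass == int(sizes.sum())

    @pytest.mark.parametrize("bad", [[], [0, 2], [-1]])
    def test_invalid_input(self, bad):
        with pytest.raises(ValueError):
            log_term_histogram(bad)


class TestTransportCost:
    def test_dirac_cost_zero_for_singletons(self):
        assert dirac_transport_cost(log_term_histogram([1, 1, 1])) == 0.0

    @pytest.mark.parametrize("sizes,expected", [
        ([3, 2], (math.log(math.factorial(3)) + math.log(2)) / 5),
        ([4], math.log(24) / 4),
    ])
    def test_dirac_cost_closed_form(self, sizes, expected):
        assert dirac_transport_cost(log_term_histogram(sizes)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n,expected", [(2, math.log(2) / 2), (4, math.log(24) / 4)])
    def test_max_cost(self, n, expected):
        assert max_transport_cost(n) == pytest.approx(expected, rel=1e-12)

    def test_max_cost_degenerate(self):
        with pytest.raises(ValueError):
            max_transport_cost(1)

    @pytest.mark.parametrize("sizes,n,expected", [
        ([4], 4, 1.0),
        ([1, 1, 1, 1], 4, 0.0),
        ([2, 2], 4, 2 * math.log(2) / math.log(24)),
    ])
    def test_normalized_cost(self, sizes, n, expected):
        assert normalized_cost(sizes, n) == pytest.approx(expected, abs=1e-12)

    def test_mass_mismatch(self):
        with pytest.raises(ValueError):
            normalized_cost([2, 2], 5)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_histogram_route_equals_exact_factorials(self, sizes):
        """The histogram expansion and exact factorial sums are the same quantity."""
        hist = log_term_histogram(sizes)
        exact = sum(exact_log_factorial(s) for s in sizes) / sum(sizes)
        assert dirac_transport_cost(hist) == pytest.approx(exact, abs=1e-10)


class TestWdist:
    def test_two_stripes_exact(self):
        res = wdist(CategoricalRaster(np.array([[1, 1], [2, 2]])), 4)
        wc = exact_normalized_cost([2, 2], 4)
        assert res.wc == pytest.approx(wc, abs=1e-12)
        assert res.ws == pytest.approx(wc, abs=1e-12)
        assert res.wdist == pytest.approx((1 - wc) ** 2, abs=1e-12)

    @pytest.mark.parametrize("rows,cols", [(2, 2), (3, 5), (8, 8)])
    def test_extremes(self, rows, cols):
        assert wdist(make_fixture("uniform", rows, cols), 4).wdist == pytest.approx(0.0, abs=1e-12)
        assert wdist(make_fixture("all_distinct", rows, cols), 4).wdist == pytest.approx(1.0, abs=1e-12)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            wdist(CategoricalRaster(np.array([[1]])), 4)

    def test_wdist_identity_and_bounds(self, rng):
        for _ in range(60):
            raster = random_raster(rng)
            for conn in (4, 8):
                res = wdist(raster, conn)
                assert 0.0 <= res.wc <= 1.0 and 0.0 <= res.ws <= 1.0
                assert res.wdist == pytest.approx((1 - res.wc) * (1 - res.ws), abs=1e-12)

    def test_connectivity_monotone(self, rng):
        """Merging patches under 8-connectivity never lowers Ws, never raises Wdist."""
        for _ in range(60):
            raster = random_raster(rng)
            r4, r8 = wdist(raster, 4), wdist(raster, 8)
            assert r8.ws >= r4.ws - 1e-12
            assert r8.wdist <= r4.wdist + 1e-12

    def test_wc_permutation_invariant(self, rng):
        raster = random_raster(rng, max_side=10)
        flat = np.asarray(raster.values).ravel()
        for _ in range(10):
            shuffled = CategoricalRaster(rng.permutation(flat).reshape(raster.shape))
            for conn in (4, 8):
                assert wdist(shuffled, conn).wc == pytest.approx(wdist(raster, conn).wc, abs=1e-12)

    def test_relabeling_invariant(self, rng):
        raster = random_raster(rng)
        relabeled = CategoricalRaster(1000 - np.asarray(raster.values) * 7)
        for conn in (4, 8):
            a, b = wdist(raster, conn), wdist(relabeled, conn)
            assert (a.wc, a.ws, a.wdist, a.s_absolute) == pytest.approx(
                (b.wc, b.ws, b.wdist, b.s_absolute), abs=1e-12
            )


class TestAbsoluteEntropy:
    @pytest.mark.parametrize("values,conn,expected", [
        ([[1, 1], [2, 2]], 4, math.log(24 / 16)),
        ([[0, 1], [2, 3]], 4, math.log(24)),
        ([[5, 5], [5, 5]], 4, -math.log(24)),
    ])
    def test_exact_small_cases(self, values, conn, expected):
        s = absolute_entropy(CategoricalRaster(np.array(values)), conn)
        assert s == pytest.approx(expected, abs=1e-9)

    def test_matches_exact_factorial_oracle(self, rng):
        """Log-gamma route agrees with big-integer factorials for N <= 20."""
        for _ in range(30):
            raster = random_raster(rng, max_side=4, max_classes=4)
            comp = class_composition(raster)
            for conn in (4, 8):
                inv = component_inventory(raster, conn)
                expected = (
                    exact_log_factorial(comp.n_total)
                    - sum(exact_log_factorial(c) for c in comp.counts.values())
                    - sum(exact_log_factorial(s) for s in inv.all_sizes())
                )
                assert absolute_entropy(raster, conn) == pytest.approx(expected, abs=1e-9)

    def test_all_distinct_is_log_n_factorial(self):
        raster = make_fixture("all_distinct", 4, 5)
        assert absolute_entropy(raster, 4) == pytest.approx(exact_log_factorial(20), abs=1e-9)
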