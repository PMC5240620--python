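import itertools

import numpy as np
import pytest
import shapely

from dasypop import (
    CoarseGrid,
    DistanceLayer,
    FineGrid,
    GridGeometry,
    UniquePopulation,
    build_urban_mask,
    compute_cogs,
    distance_to_cog,
    distance_to_roads,
    inverse_rescale,
    make_unique_population,
)
from dasypop.core_grids import block_of, pixel_center
from dasypop.ranking import round_half_away

from conftest import grid_from


def brute_point_to_segments(px, py, segments):
    """Independent min point-to-segment distance over all segments."""
    best = np.inf
    for (x1, y1), (x2, y2) in segments:
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / L2))
        best = min(best, np.hypot(px - (x1 + t * dx), py - (y1 + t * dy)))
    return best


class TestDistanceToRoads:
    def test_vertical_road_linear_in_lon(self, geom_small):
        road = [(2.0, 0.0), (2.0, -6.0)]  # along lon=2
        layer = distance_to_roads([road], geom_small)
        for col in range(6):
            lon, _ = pixel_center(geom_small, 0, col)
            assert layer.grid.values[0, col] == pytest.approx(abs(lon - 2.0))

    def test_pixel_center_on_vertex_is_zero(self, geom_small):
        lon, lat = pixel_center(geom_small, 3, 4)
        layer = distance_to_roads([[(lon, lat), (lon + 2, lat + 1)]], geom_small)
        assert layer.grid.values[3, 4] == 0.0

    def test_diagonal_segment_matches_brute_force(self):
        g = GridGeometry(0, 0, 1.0, 5, 5, 5)
        segments = [((0.2, -0.7), (4.6, -4.1))]
        layer = distance_to_roads([list(segments[0])], g)
        for r in range(5):
            for c in range(5):
                lon, lat = pixel_center(g, r, c)
                assert layer.grid.values[r, c] == pytest.approx(
                    brute_point_to_segments(lon, lat, segments), abs=1e-12
                )

    def test_empty_road_set_rejected(self, geom_small):
        with pytest.raises(ValueError, match="empty road set"):
            distance_to_roads([], geom_small)

    def test_degenerate_polyline_rejected(self, geom_small):
        with pytest.raises(ValueError):
            distance_to_roads([[(1.0, 1.0)]], geom_small)


class TestComputeCogs:
    def test_point_mass(self, geom_small):
        values = np.zeros((6, 6))
        values[1, 2] = 7.0
        cogs = compute_cogs(grid_from(geom_small, values))
        assert tuple(cogs[0, 0]) == pixel_center(geom_small, 1, 2)

    def test_uniform_population_gives_cell_center(self, geom_small):
        cogs = compute_cogs(grid_from(geom_small, np.ones((6, 6))))
        # 3x3 block of 1-degree pixels starting at origin: center (1.5, -1.5)
        assert cogs[0, 0] == pytest.approx((1.5, -1.5))

    def test_weights_1_to_9_match_weighted_mean(self, geom_small):
        values = np.zeros((6, 6))
        values[:3, :3] = np.arange(1, 10).reshape(3, 3)
        cogs = compute_cogs(grid_from(geom_small, values))
        lons = np.array([pixel_center(geom_small, r, c)[0] for r in range(3) for c in range(3)])
        lats = np.array([pixel_center(geom_small, r, c)[1] for r in range(3) for c in range(3)])
        w = np.arange(1, 10)
        assert cogs[0, 0, 0] == pytest.approx(np.average(lons, weights=w))
        assert cogs[0, 0, 1] == pytest.approx(np.average(lats, weights=w))

    def test_empty_cell_falls_back_to_geometric_center(self, geom_small):
        cogs = compute_cogs(grid_from(geom_small, np.zeros((6, 6))))
        assert cogs[1, 1] == pytest.approx((4.5, -4.5))


class TestDistanceToCog:
    def test_pixel_at_cog_is_zero_and_radially_monotone(self, geom_small):
        values = np.zeros((6, 6))
        values[4, 4] = 1.0
        pop = grid_from(geom_small, values)
        layer = distance_to_cog(compute_cogs(pop), geom_small)
        assert layer.grid.values[4, 4] == 0.0
        # within the mass pixel's own coarse cell, distance grows moving away along the row
        assert layer.grid.values[4, 4] < layer.grid.values[4, 3]
        assert layer.grid.values[4, 4] < layer.grid.values[3, 4] < layer.grid.values[5, 3]

    def test_hand_computed_cell(self, geom_small):
        values = np.zeros((6, 6))
        values[:3, :3] = np.array([[1, 0, 0], [0, 0, 0], [0, 0, 1]])
        pop = grid_from(geom_small, values)
        cogs = compute_cogs(pop)
        assert cogs[0, 0] == pytest.approx((1.5, -1.5))  # midpoint of the two masses
        layer = distance_to_cog(cogs, geom_small)
        assert layer.grid.values[0, 0] == pytest.approx(np.hypot(1.0, 1.0))

    def test_undefined_cog_rejected(self, geom_small):
        cogs = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="undefined"):
            distance_to_cog(cogs, geom_small)


class TestInverseRescale:
    def test_extremes_map_to_bounds(self, geom_small, rng):
        dist = DistanceLayer(grid_from(geom_small, rng.uniform(0, 3, (6, 6))))
        out = inverse_rescale(dist)
        i_min = np.unravel_index(np.argmin(dist.grid.values), (6, 6))
        i_max = np.unravel_index(np.argmax(dist.grid.values), (6, 6))
        assert out.values[i_min] == pytest.approx(1.1e-5, abs=1e-20)
        assert out.values[i_max] == pytest.approx(1.0e-5, abs=1e-20)

    def test_two_value_layer_hits_endpoints(self, geom_small):
        values = np.ones((6, 6))
        values[0, 0] = 0.0
        out = inverse_rescale(DistanceLayer(grid_from(geom_small, values)))
        assert out.values[0, 0] == pytest.approx(1.1e-5)
        assert out.values[5, 5] == pytest.approx(1.0e-5)

    def test_rank_order_reverses_distance_order(self, rng):
        g = GridGeometry(0, 0, 0.1, 10, 10, 10)
        d = rng.uniform(0, 5, (10, 10))
        out = inverse_rescale(DistanceLayer(FineGrid(g, d, np.ones((10, 10), bool))))
        assert (np.argsort(out.values.ravel()) == np.argsort(-d.ravel())).all()

    def test_constant_layer_rejected(self, geom_small):
        with pytest.raises(ValueError, match="identical"):
            inverse_rescale(DistanceLayer(grid_from(geom_small, np.ones((6, 6)))))

    def test_bad_bounds_rejected(self, geom_small, rng):
        dist = DistanceLayer(grid_from(geom_small, rng.uniform(0, 1, (6, 6))))
        with pytest.raises(ValueError):
            inverse_rescale(dist, lo=2e-5, hi=1e-5)


class TestUniquePopulation:
    def _layers(self, geom, rng):
        road = inverse_rescale(DistanceLayer(grid_from(geom, rng.uniform(0, 2, geom.fine_shape))))
        cog = inverse_rescale(DistanceLayer(grid_from(geom, rng.uniform(0, 2, geom.fine_shape))))
        return road, cog

    def test_equal_populations_become_distinct(self, geom_small, rng):
        pop = grid_from(geom_small, np.full((6, 6), 5.0))
        road, cog = self._layers(geom_small, rng)
        up = make_unique_population(pop, road, cog)
        cell = up.grid.values[:3, :3].ravel()
        assert len(np.unique(cell)) == cell.size

    def test_zero_population_gives_pure_perturbation(self, geom_small, rng):
        pop = grid_from(geom_small, np.zeros((6, 6)))
        road, cog = self._layers(geom_small, rng)
        up = make_unique_population(pop, road, cog)
        assert (up.grid.values > 2.0e-5).all()
        assert (up.grid.values <= 2.2e-5).all()

    def test_perturbation_never_reorders_distinct_populations(self, rng):
        g = GridGeometry(0, 0, 0.5, 6, 12, 12)
        for _ in range(20):
            pop_vals = np.round(rng.uniform(0, 100, (12, 12)), 4)  # gaps >> 2.2e-5
            pop = FineGrid(g, pop_vals, np.ones((12, 12), bool))
            road = inverse_rescale(DistanceLayer(FineGrid(g, rng.uniform(0, 2, (12, 12)), np.ones((12, 12), bool))))
            cog = inverse_rescale(DistanceLayer(FineGrid(g, rng.uniform(0, 2, (12, 12)), np.ones((12, 12), bool))))
            up = make_unique_population(pop, road, cog)
            flat_pop, flat_up = pop_vals.ravel(), up.grid.values.ravel()
            gap = np.abs(flat_pop[:, None] - flat_pop[None, :]) > 2.2e-5
            order_pop = flat_pop[:, None] > flat_pop[None, :]
            order_up = flat_up[:, None] > flat_up[None, :]
            assert (order_pop == order_up)[gap].all()

    def test_perturbation_bounded_by_sum_of_maxima(self, geom_small, rng):
        pop = grid_from(geom_small, rng.uniform(0, 10, (6, 6)))
        road, cog = self._layers(geom_small, rng)
        up = make_unique_population(pop, road, cog)
        bound = road.values.max() + cog.values.max()
        assert bound <= 2.2e-5 + 1e-18
        assert np.abs(up.grid.values - pop.values)[pop.valid_mask].max() <= bound + 1e-18

    def test_geometry_mismatch_rejected(self, geom_small, rng):
        other = GridGeometry(1.0, 0.0, 1.0, 3, 6, 6)
        pop = grid_from(geom_small, np.ones((6, 6)))
        road = FineGrid(other, np.ones((6, 6)) * 1e-5, np.ones((6, 6), bool))
        with pytest.raises(ValueError, match="geometry"):
            make_unique_population(pop, road, road)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.5, 2), (2.5, 3), (3.15, 3), (3.5, 4), (0.49, 0), (0.0, 0)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


def brute_force_top_k(values, valid, k):
    """Best k-subset of valid pixels by total value, via full enumeration."""
    idx = [i for i in range(values.size) if valid.ravel()[i]]
    best, best_set = -np.inf, None
    for subset in itertools.combinations(idx, k):
        s = values.ravel()[list(subset)].sum()
        if s > best:
            best, best_set = s, set(subset)
    return best_set


class TestBuildUrbanMask:
    def _unique(self, geom, values, valid=None):
        return UniquePopulation(grid_from(geom, values, valid))

    def test_top_half_selected(self):
        g = GridGeometry(0, 0, 1.0, 2, 2, 2)
        up = self._unique(g, [[5, 3], [2, 1]])
        frac = CoarseGrid(g, np.array([[0.5]]), np.ones((1, 1), bool))
        mask = build_urban_mask(up, frac)
        assert mask.urban.tolist() == [[True, True], [False, False]]

    @pytest.mark.parametrize("fraction,count", [(0.0, 0), (1.0, 9)])
    def test_fraction_endpoints(self, geom_small, rng, fraction, count):
        up = self._unique(geom_small, rng.uniform(0, 9, (6, 6)))
        frac = CoarseGrid(geom_small, np.full((2, 2), fraction), np.ones((2, 2), bool))
        mask = build_urban_mask(up, frac)
        assert mask.urban[:3, :3].sum() == count

    def test_fraction_035_selects_three_and_matches_enumeration(self, rng):
        g = GridGeometry(0, 0, 1.0, 3, 3, 3)
        values = rng.uniform(0, 9, (3, 3))
        up = self._unique(g, values)
        frac = CoarseGrid(g, np.array([[0.35]]), np.ones((1, 1), bool))
        mask = build_urban_mask(up, frac)
        chosen = set(np.flatnonzero(mask.urban.ravel()))
        assert len(chosen) == 3  # round(0.35 * 9) = round(3.15) = 3
        assert chosen == brute_force_top_k(values, np.ones((3, 3), bool), 3)

    def test_separation_property_and_counting(self, rng):
        g = GridGeometry(0, 0, 0.5, 4, 8, 8)
        values = rng.uniform(0, 50, (8, 8))
        valid = rng.uniform(size=(8, 8)) > 0.2
        up = UniquePopulation(FineGrid(g, values, valid))
        fracs = rng.uniform(0, 1, (2, 2))
        frac = CoarseGrid(g, fracs, np.ones((2, 2), bool))
        mask = build_urban_mask(up, frac)
        total = 0
        for cr in range(2):
            for cc in range(2):
                rows, cols = block_of(g, cr, cc)
                v = values[rows, cols].ravel()
                m = mask.urban[rows, cols].ravel()
                va = valid[rows, cols].ravel()
                k = min(int(round_half_away(fracs[cr, cc] * 16)), int(va.sum()))
                assert m.sum() == k
                total += k
                if m.any() and (va & ~m).any():
                    assert v[m].min() >= v[va & ~m].max()
        assert mask.urban_count() == total

    def test_water_never_urbanized(self, geom_small, rng):
        valid = np.zeros((6, 6), bool)
        valid[0, 0] = True  # one land pixel in cell (0,0)
        up = UniquePopulation(FineGrid(geom_small, rng.uniform(0, 5, (6, 6)), valid))
        frac = CoarseGrid(geom_small, np.ones((2, 2)), np.ones((2, 2), bool))
        mask = build_urban_mask(up, frac)
        assert mask.urban_count() == 1
        assert mask.urban[0, 0]

    def test_fraction_out_of_range_rejected(self, geom_small, rng):
        up = self._unique(geom_small, rng.uniform(0, 5, (6, 6)))
        frac = CoarseGrid(geom_small, np.full((2, 2), 0.5), np.ones((2, 2), bool))
        frac.values[0, 0] = 1.5
        with pytest.raises(ValueError, match="outside"):
            build_urban_mask(up, frac)

    def test_bit_identical_determinism(self, geom_small, rng):
        values = rng.uniform(0, 5, (6, 6))
        up = self._unique(geom_small, values)
        frac = CoarseGrid(geom_small, np.full((2, 2), 0.4), np.ones((2, 2), bool))
        m1 = build_urban_mask(up, frac)
        m2 = build_urban_mask(self._unique(geom_small, values.copy()), frac)
        assert (m1.urban == m2.urban).all()

    def test_exact_ties_broken_by_row_major_index(self):
        g = GridGeometry(0, 0, 1.0, 2, 2, 2)
        up = self._unique(g, [[1.0, 1.0], [1.0, 1.0]])
        frac = CoarseGrid(g, np.array([[0.5]]), np.ones((1, 1), bool))
        mask = build_urban_mask(up, frac)
        assert mask.urban.tolist() == [[True, True], [False, False]]
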