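"""Occupancy weighting, isodose thresholds, and contour export."""

import numpy as np
import pytest

from isomap.isodose import (DoseDensityGrid, STANDARD_HOURS, contours_geojson,
                            export_contours, isodose_threshold,
                            occupancy_from_hours, primary_dose_factor,
                            single_point_occupancy, weighted_density)
from tests.conftest import synthetic_kerma_grid


def grid_from_cells(cells, far_field=0.0):
    """Pad a small cell list into a DoseDensityGrid (rest zero)."""
    values = np.zeros((35, 30))
    values.ravel()[:len(cells)] = cells
    return DoseDensityGrid(values=values, far_field=far_field)


class TestOccupancy:
    def test_standard_hours_normalise(self, wooden_house):
        occ = occupancy_from_hours(STANDARD_HOURS, wooden_house)
        assert occ.total_hours == pytest.approx(14.0)
        assert occ.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert occ.factor(1) == pytest.approx(8.0 / 14.0)   # bedroom
        assert occ.factor(9) == pytest.approx(1.0 / 14.0)   # kitchen
        assert occ.factor(5) == 0.0                         # corridor: no hours

    def test_single_room(self, wooden_house):
        occ = occupancy_from_hours({"living": 5.0}, wooden_house)
        assert occ.factor(10) == 1.0
        assert occ.p.sum() == pytest.approx(1.0)

    def test_two_room_symmetry(self, wooden_house):
        occ = occupancy_from_hours({"kitchen": 2.0, "dining": 2.0}, wooden_house)
        assert occ.factor(9) == occ.factor(11) == 0.5

    def test_all_zero_hours_rejected(self, wooden_house):
        with pytest.raises(ValueError):
            occupancy_from_hours({"kitchen": 0.0}, wooden_house)

    def test_unknown_room_rejected(self, wooden_house):
        with pytest.raises(KeyError):
            occupancy_from_hours({"garage": 1.0}, wooden_house)


class TestWeightedDensity:
    def _two_grids(self):
        rng = np.random.default_rng(3)
        v1 = rng.uniform(0, 2, (35, 30))
        v2 = rng.uniform(0, 2, (35, 30))
        g1 = synthetic_kerma_grid(1, 0.0, v1, far_field=5.0)
        g2 = synthetic_kerma_grid(2, 0.0, v2, far_field=7.0)
        return g1, g2

    def _occ(self, p1):
        from isomap.isodose import OccupancyProfile
        return OccupancyProfile(hours={}, point_order=(1, 2),
                                p=np.array([p1, 1 - p1]))

    def test_degenerate_occupancy_reduces_to_single_point(self):
        g1, g2 = self._two_grids()
        out = weighted_density([g1, g2], self._occ(1.0))
        assert np.array_equal(out.values, g1.values)
        assert out.far_field == g1.far_field

    def test_identical_grids_invariant(self):
        g1, _ = self._two_grids()
        g1b = synthetic_kerma_grid(2, 0.0, g1.values, far_field=g1.far_field)
        out = weighted_density([g1, g1b], self._occ(0.3))
        assert np.allclose(out.values, g1.values)

    def test_total_matches_direct_sum_oracle(self):
        g1, g2 = self._two_grids()
        occ = self._occ(0.25)
        out = weighted_density([g1, g2], occ)
        oracle = 0.25 * g1.total_infinite + 0.75 * g2.total_infinite
        assert out.total == pytest.approx(oracle, rel=1e-12)
        assert primary_dose_factor([g1, g2], occ) == pytest.approx(oracle)

    def test_shape_mismatch_rejected(self):
        g1, g2 = self._two_grids()
        g2.values = g2.values[:10, :10]
        with pytest.raises(ValueError):
            weighted_density([g1, g2], self._occ(0.5))

    def test_occupancy_weighted_density_on_fixture(self, wooden_grids,
                                                   standard_occupancy):
        from isomap.transport import grids_by_depth
        g0 = grids_by_depth(wooden_grids, 0.0)
        out = weighted_density(g0, standard_occupancy)
        oracle = sum(w * g.total_infinite
                     for w, g in zip(standard_occupancy.p, g0))
        assert out.total == pytest.approx(oracle, rel=1e-9)


class TestIsodoseThreshold:
    def test_simple_ranked_cells(self):
        res = isodose_threshold(grid_from_cells([5.0, 3.0, 1.0, 1.0]), k=0.8)
        assert res.mask.sum() == 2
        assert res.k_achieved == pytest.approx(0.8)
        assert res.threshold == pytest.approx(3.0)
        assert res.enclosed_area == pytest.approx(2.0)
        assert not res.unreachable

    def test_uniform_grid_minimal_area(self):
        res = isodose_threshold(grid_from_cells([1.0] * 100), k=0.25)
        assert res.mask.sum() == 25
        assert res.k_achieved == pytest.approx(0.25)

    def test_far_field_dominated_flagged_unreachable(self):
        res = isodose_threshold(grid_from_cells([4.0, 3.0, 2.0, 1.0],
                                                far_field=10.0), k=0.9)
        assert res.unreachable
        assert res.k_achieved == pytest.approx(0.5)
        assert res.mask.sum() == 4  # all source cells

    def test_invalid_k_rejected(self):
        grid = grid_from_cells([1.0])
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                isodose_threshold(grid, bad)

    def test_mask_nesting_and_conservation(self):
        rng = np.random.default_rng(11)
        grid = grid_from_cells(rng.uniform(0, 1, 300), far_field=rng.uniform(0, 50))
        prev = None
        for k in (0.1, 0.2, 0.3, 0.4):
            res = isodose_threshold(grid, k)
            if res.unreachable:
                continue
            masked = grid.values[res.mask].sum()
            unmasked = grid.values[~res.mask].sum()
            assert masked + unmasked + grid.far_field == pytest.approx(
                grid.total, rel=1e-9)
            if prev is not None:
                assert np.all(res.mask | ~prev.mask)  # prev mask subset of new
                assert res.enclosed_area >= prev.enclosed_area
            prev = res

    def test_weighted_degenerate_matches_single_point(self):
        """Isodose of a weighted density with one-point occupancy equals the
        single-point isodose."""
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, (35, 30))
        g = synthetic_kerma_grid(4, 0.0, v, far_field=3.0)
        from isomap.isodose import OccupancyProfile
        occ = OccupancyProfile(hours={}, point_order=(4,), p=np.array([1.0]))
        dens = weighted_density([g], occ)
        direct = DoseDensityGrid(values=v, far_field=3.0)
        r1 = isodose_threshold(dens, 0.3)
        r2 = isodose_threshold(direct, 0.3)
        assert np.array_equal(r1.mask, r2.mask)
        assert r1.threshold == r2.threshold


def _boundary_edges(mask):
    """Independent oracle: cell edges adjacent to exactly one masked cell."""
    padded = np.pad(mask, 1)
    edges = 0
    edges += np.sum(padded[1:, :] != padded[:-1, :])
    edges += np.sum(padded[:, 1:] != padded[:, :-1])
    return edges


class TestContours:
    def _result(self, mask):
        from isomap.isodose import IsodoseResult
        return IsodoseResult(k=0.5, threshold=1.0, mask=mask,
                             k_achieved=0.5, enclosed_area=float(mask.sum()))

    def test_single_cell_square(self):
        mask = np.zeros((35, 30), dtype=bool)
        mask[3, 4] = True
        polys = export_contours(self._result(mask))
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(1.0)
        assert polys[0].length == pytest.approx(4.0)

    def test_two_by_two_block(self):
        mask = np.zeros((35, 30), dtype=bool)
        mask[5:7, 5:7] = True
        polys = export_contours(self._result(mask))
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(4.0)
        assert polys[0].length == pytest.approx(8.0)

    def test_l_shape_against_edge_walk_oracle(self):
        mask = np.zeros((35, 30), dtype=bool)
        mask[10, 10] = mask[11, 10] = mask[11, 11] = True
        polys = export_contours(self._result(mask))
        assert sum(p.area for p in polys) == pytest.approx(3.0)
        assert sum(p.length for p in polys) == pytest.approx(
            _boundary_edges(mask))

    def test_empty_mask(self):
        mask = np.zeros((35, 30), dtype=bool)
        assert export_contours(self._result(mask)) == []

    def test_geojson_properties(self):
        mask = np.zeros((35, 30), dtype=bool)
        mask[0, 0] = True
        gj = contours_geojson(self._result(mask))
        assert gj["type"] == "FeatureCollection"
        props = gj["features"][0]["properties"]
        assert props["k"] == 0.5 and "ID_k" in props
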