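"""Access-planning tests: plane fit, dynamic grid, capsule casting, heat map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcmorph.grids import CELL_LABELS
from rcmorph.planning import (HeatMap, PlanningError, TrajectoryResult,
                              aggregate_heatmap, build_dynamic_grid,
                              cast_trajectory, depth_report, evaluate_specimen,
                              fit_rw_plane)
from rcmorph.volume import LabelledVolume


def disc_volume(normal=(1.0, 0.0, 0.0), center=(2.0, 0.0, 0.0), spacing=0.02,
                semiaxes=(0.8, 0.6), with_tube_at=None, artery_at=None):
    """Small volume with a membrane disc (label 4), a perilymph blob (2) on
    the inward side, optionally a canal tube (3) and artery (5) deep to it."""
    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    c = np.asarray(center, dtype=float)
    shape = (260, 70, 70)
    origin = np.array([-0.3, -0.7, -0.7])
    ax = [origin[d] + np.arange(shape[d]) * spacing for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    grid = np.zeros(shape, dtype=np.uint8)

    ref = np.array([0.0, 0.0, 1.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    W = np.stack([X - c[0], Y - c[1], Z - c[2]])
    dn = np.einsum("i,i...->...", n, W)
    d1 = np.einsum("i,i...->...", e1, W)
    d2 = np.einsum("i,i...->...", e2, W)
    disc = (np.abs(dn) <= 0.04) & ((d1 / semiaxes[1])**2 + (d2 / semiaxes[0])**2 <= 1)
    # perilymph blob deep to the membrane (inward = -n side)
    blob = ((X - (c[0] - 1.0 * n[0]))**2 + (Y - (c[1] - 1.0 * n[1]))**2
            + (Z - (c[2] - 1.0 * n[2]))**2) <= 0.4**2
    grid[blob] = 2
    grid[disc] = 4
    if with_tube_at is not None:
        # tube along z at depth `with_tube_at` inward from the center
        tc = c - with_tube_at * n
        tube = ((X - tc[0])**2 + (Y - tc[1])**2) <= 0.25**2
        grid[tube] = 3
    if artery_at is not None:
        acenter = c - artery_at * n
        art = ((X - acenter[0])**2 + (Y - acenter[1])**2) <= 0.1**2
        grid[art] = 5
    return LabelledVolume(grid=grid, spacing=spacing, origin=origin)


class TestPlaneFit:
    def test_known_disc_normal_recovered(self):
        vol = disc_volume(normal=(0.9, -0.3, 0.1))
        (center, normal), _ = fit_rw_plane(vol)
        true_n = np.array([0.9, -0.3, 0.1]) / np.linalg.norm([0.9, -0.3, 0.1])
        angle = np.degrees(np.arccos(np.clip(abs(normal @ true_n), -1, 1)))
        assert angle < 1.0
        assert np.allclose(center, [2.0, 0.0, 0.0], atol=0.05)
        # oriented away from the perilymph blob
        assert normal @ true_n > 0

    def test_flipped_geometry_flips_normal(self):
        vol = disc_volume(normal=(-1.0, 0.0, 0.0), center=(2.0, 0.0, 0.0))
        # same disc plane, but perilymph now sits on the +x side
        (_, normal), _ = fit_rw_plane(vol)
        assert normal[0] < 0

    def test_missing_membrane_errors(self):
        vol = LabelledVolume(grid=np.zeros((8, 8, 8), dtype=np.uint8), spacing=0.02)
        with pytest.raises(PlanningError, match="label 4"):
            fit_rw_plane(vol)


class TestDynamicGrid:
    def _plane(self):
        n = np.array([1.0, 0.0, 0.0])
        e_sup = np.array([0.0, 0.0, 1.0])
        e_ant = np.cross(e_sup, n)
        return (np.zeros(3), n), (e_sup, e_ant)

    def _square_points(self, half):
        plane, (e_sup, e_ant) = self._plane()
        uu, vv = np.meshgrid(np.linspace(-half, half, 21),
                             np.linspace(-half, half, 21))
        return (uu.ravel()[:, None] * e_ant + vv.ravel()[:, None] * e_sup)

    def test_unit_square_cell_size(self):
        plane, basis = self._plane()
        grid = build_dynamic_grid(plane, basis, self._square_points(0.5))
        assert grid.cell_size == pytest.approx((0.25, 0.25))

    def test_grid_scales_with_membrane(self):
        plane, basis = self._plane()
        g1 = build_dynamic_grid(plane, basis, self._square_points(0.5))
        g2 = build_dynamic_grid(plane, basis, self._square_points(0.75))
        assert np.allclose(np.array(g2.cell_size), 1.5 * np.array(g1.cell_size))
        assert set(g1.cell_centers) == set(g2.cell_centers) == set(CELL_LABELS)

    def test_cells_inside_bounding_box(self):
        plane, basis = self._plane()
        grid = build_dynamic_grid(plane, basis, self._square_points(0.5))
        (_, n), (e_sup, e_ant) = plane, basis
        for c in CELL_LABELS:
            rel = grid.cell_centers[c]
            assert grid.ant_range[0] <= rel @ e_ant <= grid.ant_range[1]
            assert grid.sup_range[0] <= rel @ e_sup <= grid.sup_range[1]
            assert abs(rel @ n) < 1e-9  # coplanar

    def test_row_a_is_superior_col_1_is_anterior(self):
        plane, basis = self._plane()
        grid = build_dynamic_grid(plane, basis, self._square_points(0.5))
        e_sup, e_ant = basis
        assert grid.cell_centers["A2"] @ e_sup > grid.cell_centers["D2"] @ e_sup
        assert grid.cell_centers["B1"] @ e_ant > grid.cell_centers["B4"] @ e_ant

    def test_degenerate_projection_errors(self):
        plane, basis = self._plane()
        pts = np.zeros((5, 3))
        with pytest.raises(PlanningError, match="degenerate"):
            build_dynamic_grid(plane, basis, pts)


class TestCasting:
    def test_first_contact_depth_closed_form(self):
        # tube of radius 0.25 centered 3.5 mm along the inward normal;
        # capsule of radius 0.2 first touches at 3.5 - 0.25 - 0.2 = 3.05
        vol = disc_volume(center=(4.0, 0.0, 0.0), with_tube_at=3.5)
        res = cast_trajectory(vol, origin=np.array([4.0, 0.0, 0.0]),
                              direction=np.array([-1.0, 0.0, 0.0]),
                              drill_radius=0.2, depth_limit=4.0)
        assert res.hit_rc
        assert res.depth_to_rc == pytest.approx(3.05, abs=3 * vol.spacing)
        assert not res.artery_collision

    def test_empty_ray_misses(self):
        vol = disc_volume(center=(4.0, 0.0, 0.0))  # no tube
        res = cast_trajectory(vol, origin=np.array([4.0, 0.0, 0.0]),
                              direction=np.array([-1.0, 0.0, 0.0]))
        assert not res.hit_rc and res.depth_to_rc is None

    def test_artery_before_canal_collides(self):
        vol = disc_volume(center=(4.0, 0.0, 0.0), with_tube_at=3.5, artery_at=1.0)
        res = cast_trajectory(vol, origin=np.array([4.0, 0.0, 0.0]),
                              direction=np.array([-1.0, 0.0, 0.0]))
        assert res.hit_rc and res.artery_collision

    def test_artery_beyond_target_ignored(self):
        # artery deeper than the canal contact: drilling stops at target
        vol = disc_volume(center=(4.0, 0.0, 0.0), with_tube_at=2.0, artery_at=3.6)
        res = cast_trajectory(vol, origin=np.array([4.0, 0.0, 0.0]),
                              direction=np.array([-1.0, 0.0, 0.0]))
        assert res.hit_rc and not res.artery_collision

    def test_origin_outside_errors(self):
        vol = disc_volume()
        with pytest.raises(PlanningError, match="outside"):
            cast_trajectory(vol, origin=np.array([50.0, 0.0, 0.0]),
                            direction=np.array([-1.0, 0.0, 0.0]))

    def test_blocked_cell_not_evaluable(self):
        vol = disc_volume(center=(4.0, 0.0, 0.0), with_tube_at=3.5)
        res = cast_trajectory(vol, origin=np.array([4.0, 0.0, 0.0]),
                              direction=np.array([-1.0, 0.0, 0.0]),
                              cell="D1", blocked_by_stapedius=True)
        assert res.blocked_by_stapedius and not res.evaluable and not res.hit_rc


class TestEvaluateSpecimen:
    def test_mini_specimen_structure(self, mini_specimen):
        params, _, vol = mini_specimen
        plane, basis = fit_rw_plane(vol)
        membrane = vol.origin + np.argwhere(vol.grid == 4) * vol.spacing
        grid = build_dynamic_grid(plane, basis, membrane)
        results = evaluate_specimen(vol, grid, depth_limit=3.5)
        assert sorted(r.cell for r in results) == sorted(CELL_LABELS)
        by_cell = {r.cell: r for r in results}
        # stapedius occludes D1 (detected geometrically from label 6)
        assert not by_cell["D1"].evaluable
        # the canal lies deep to the superior-middle cells by construction
        assert any(by_cell[c].hit_rc for c in ("A2", "A3", "B2", "B3"))

    def test_hit_monotone_in_drill_radius_and_depth(self, mini_specimen):
        _, _, vol = mini_specimen
        plane, basis = fit_rw_plane(vol)
        membrane = vol.origin + np.argwhere(vol.grid == 4) * vol.spacing
        grid = build_dynamic_grid(plane, basis, membrane)

        def hits(drill, depth):
            res = evaluate_specimen(vol, grid, drill_radius=drill, depth_limit=depth)
            return {r.cell for r in res if r.hit_rc}

        h1 = hits(0.1, 3.5)
        h2 = hits(0.2, 3.5)
        h3 = hits(0.35, 3.5)
        assert h1 <= h2 <= h3
        d1 = hits(0.2, 2.8)
        d2 = hits(0.2, 3.8)
        assert d1 <= d2


def make_result(cell, hit=False, depth=None, artery=False, blocked=False):
    return TrajectoryResult(cell=cell, hit_rc=hit,
                            depth_to_rc=depth if hit else None,
                            artery_collision=artery,
                            blocked_by_stapedius=blocked,
                            evaluable=not blocked)


def synthetic_cohort(n=10, hit_cells=("A2",), miss_in=(), artery_cells=(),
                     blocked_cells=("D1",)):
    cohort = []
    for k in range(n):
        results = []
        for c in CELL_LABELS:
            if c in blocked_cells:
                results.append(make_result(c, blocked=True))
            elif c in hit_cells and k not in miss_in:
                results.append(make_result(c, hit=True, depth=3.5,
                                           artery=c in artery_cells))
            else:
                results.append(make_result(c, artery=c in artery_cells))
        cohort.append(results)
    return cohort


class TestHeatMap:
    def test_nine_of_ten_is_90_percent(self):
        cohort = synthetic_cohort(10, hit_cells=("A2",), miss_in=(4,))
        hm = aggregate_heatmap(cohort)
        assert hm.freq[0, 1] == pytest.approx(0.9)
        assert hm.n_evaluable[0, 1] == 10

    def test_blocked_cell_is_not_applicable_not_zero(self):
        hm = aggregate_heatmap(synthetic_cohort(5))
        assert np.isnan(hm.freq[3, 0])          # D1
        assert hm.n_evaluable[3, 0] == 0

    def test_unsafe_cell_excluded_even_at_full_frequency(self):
        cohort = synthetic_cohort(10, hit_cells=("A2", "B1"), artery_cells=("B1",))
        hm = aggregate_heatmap(cohort)
        assert hm.freq[1, 0] == pytest.approx(1.0)
        assert "B1" not in hm.selected
        assert "A2" in hm.selected

    def test_all_hits_selects_all_evaluable(self):
        hit_all = tuple(c for c in CELL_LABELS if c != "D1")
        hm = aggregate_heatmap(synthetic_cohort(4, hit_cells=hit_all))
        assert hm.selected == frozenset(hit_all)

    def test_threshold_nesting(self):
        cohort = synthetic_cohort(10, hit_cells=("A2", "A3"), miss_in=(0,))
        hm_lo = aggregate_heatmap(cohort, threshold=0.8)
        hm_hi = aggregate_heatmap(cohort, threshold=0.95)
        assert hm_hi.selected <= hm_lo.selected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_frequencies_are_k_over_n(self, n_spec, seed):
        rng = np.random.default_rng(seed)
        cohort = []
        for _ in range(n_spec):
            results = [make_result(c, hit=bool(rng.random() < 0.5) if ok else False,
                                   depth=3.0, blocked=not ok)
                       for c in CELL_LABELS
                       for ok in [bool(rng.random() < 0.9)]]
            cohort.append(results)
        hm = aggregate_heatmap(cohort)
        for i in range(4):
            for j in range(4):
                if hm.n_evaluable[i, j] == 0:
                    assert np.isnan(hm.freq[i, j])
                else:
                    k = hm.freq[i, j] * hm.n_evaluable[i, j]
                    assert k == pytest.approx(round(k), abs=1e-9)
                    assert 0.0 <= hm.freq[i, j] <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(PlanningError):
            aggregate_heatmap([])
        with pytest.raises(PlanningError, match="threshold"):
            aggregate_heatmap(synthetic_cohort(2), threshold=1.5)


class TestDepthReport:
    def test_single_hit(self):
        cohort = [[make_result("A2", hit=True, depth=3.5)]
                  + [make_result(c) for c in CELL_LABELS if c != "A2"]]
        rep = depth_report(cohort)
        assert rep["min"] == rep["median"] == rep["max"] == 3.5
        assert rep["n_hits"] == 1

    def test_no_hits_flagged_empty(self):
        cohort = [[make_result(c) for c in CELL_LABELS]]
        rep = depth_report(cohort)
        assert rep["empty"] and rep["n_hits"] == 0
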