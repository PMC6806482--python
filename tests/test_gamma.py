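"""Gamma-index analysis: brute-force equivalence, threshold/normalization
semantics, criterion monotonicity, and depth-of-best-agreement recovery."""

import numpy as np
import pytest

from protonval.dose import DoseCube
from protonval.gamma import (GammaCriterion, STANDARD_CRITERIA,
                             SEARCH_RADIUS_FACTOR, subgrid_spacing,
                             depth_search, extract_plane, gamma_2d, gamma_3d,
                             resample_plane)


def brute_force_gamma_2d(ref_vals, ref_pos, fine_vals, fine_pos, dd_abs, dta):
    """Exhaustive all-pairs minimum gamma over the same fine subgrid."""
    out = np.empty(ref_vals.size)
    rmax = SEARCH_RADIUS_FACTOR * dta
    for i, (rv, rp) in enumerate(zip(ref_vals, ref_pos)):
        d2 = np.sum((fine_pos - rp) ** 2, axis=1)
        sel = d2 <= rmax ** 2
        g2 = ((fine_vals[sel] - rv) / dd_abs) ** 2 + d2[sel] / dta ** 2
        out[i] = np.sqrt(g2.min())
    return out


def _random_plane(rng, n=20, spacing=2.0):
    vals = rng.random((n, n)) * 2.0
    origin = (-spacing * (n - 1) / 2.0, -spacing * (n - 1) / 2.0)
    return vals, origin, spacing


class TestGamma2D:
    def test_identity_passes_everywhere(self):
        rng = np.random.default_rng(0)
        vals, origin, sp = _random_plane(rng)
        crit = GammaCriterion(3.0, 3.0, 5.0)
        res = gamma_2d(vals, origin, sp, vals, origin, sp, crit)
        assert res.pass_rate == 100.0
        assert res.mean_gamma == pytest.approx(0.0, abs=1e-12)

    def test_global_scaling_bound(self):
        # evaluation = 1.02 x reference: every dose difference is at most
        # 2% of the evaluation maximum, so 2%/2mm passes globally
        rng = np.random.default_rng(1)
        vals, origin, sp = _random_plane(rng)
        res = gamma_2d(vals, origin, sp, 1.02 * vals, origin, sp,
                       GammaCriterion(2.0, 2.0, 5.0))
        assert res.pass_rate == 100.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        ref, origin, sp = _random_plane(rng, n=20)
        ev = ref + 0.15 * rng.standard_normal(ref.shape)
        ev = np.clip(ev, 0.0, None)
        crit = GammaCriterion(3.0, 3.0, 5.0)
        res = gamma_2d(ref, origin, sp, ev, origin, sp, crit)

        # oracle over the identical subgrid
        sub = subgrid_spacing(sp, crit.dta_mm)
        from scipy.interpolate import RegularGridInterpolator
        ex = origin[0] + np.arange(ev.shape[0]) * sp
        ey = origin[1] + np.arange(ev.shape[1]) * sp
        interp = RegularGridInterpolator((ex, ey), ev, method="linear",
                                         bounds_error=False, fill_value=0.0)
        fx = np.arange(ex[0], ex[-1] + 1e-9, sub)
        fy = np.arange(ey[0], ey[-1] + 1e-9, sub)
        fxx, fyy = np.meshgrid(fx, fy, indexing="ij")
        fine_pos = np.stack([fxx.ravel(), fyy.ravel()], axis=1)
        fine_vals = interp(fine_pos)

        norm = ev.max()
        rx = origin[0] + np.arange(ref.shape[0]) * sp
        ry = origin[1] + np.arange(ref.shape[1]) * sp
        rxx, ryy = np.meshgrid(rx, ry, indexing="ij")
        mask = ref >= crit.threshold_percent / 100.0 * norm
        oracle = brute_force_gamma_2d(
            ref[mask], np.stack([rxx[mask], ryy[mask]], axis=1),
            fine_vals, fine_pos, crit.dose_percent / 100.0 * norm,
            crit.dta_mm)
        got = res.gamma_map[mask]
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_rescale_invariance(self):
        # multiplying both planes by c > 0 leaves every gamma unchanged
        rng = np.random.default_rng(3)
        ref, origin, sp = _random_plane(rng)
        ev = ref * (1 + 0.05 * rng.standard_normal(ref.shape))
        crit = GammaCriterion(3.0, 3.0, 10.0)
        a = gamma_2d(ref, origin, sp, ev, origin, sp, crit)
        b = gamma_2d(7.3 * ref, origin, sp, 7.3 * ev, origin, sp, crit)
        m = ~np.isnan(a.gamma_map)
        np.testing.assert_allclose(a.gamma_map[m], b.gamma_map[m], rtol=1e-12)
        assert a.pass_rate == b.pass_rate

    def test_all_below_threshold_raises(self):
        ref = np.full((5, 5), 0.01)
        ev = np.full((5, 5), 1.0)
        with pytest.raises(ValueError, match="empty"):
            gamma_2d(ref, (0, 0), 2.0, ev, (0, 0), 2.0,
                     GammaCriterion(3.0, 3.0, 5.0))

    def test_anti_monotone_in_criterion(self):
        rng = np.random.default_rng(4)
        ref, origin, sp = _random_plane(rng)
        ev = ref + 0.1 * rng.standard_normal(ref.shape)
        ev = np.clip(ev, 0.0, None)
        rates = [gamma_2d(ref, origin, sp, ev, origin, sp, c).pass_rate
                 for c in STANDARD_CRITERIA]
        assert rates[0] <= rates[1] <= rates[2]


class TestGamma3D:
    def _cube(self, rng, n=10, spacing=2.0):
        dose = rng.random((n, n, n)) + 0.5
        return DoseCube(dose=dose, spacing=[spacing] * 3,
                        origin=[0.0, 0.0, 0.0], engine_tag="apb")

    def test_points_lifted_from_cube_pass(self):
        rng = np.random.default_rng(5)
        cube = self._cube(rng)
        pts = np.stack(np.meshgrid(*[cube.axis_centers(a)[1:-1:2]
                                     for a in range(3)], indexing="ij"),
                       axis=-1).reshape(-1, 3)
        vals = cube.interp_points(pts)
        res = gamma_3d(pts, vals, cube, GammaCriterion(1.0, 1.0, 10.0))
        assert res.pass_rate == 100.0
        assert res.mean_gamma == pytest.approx(0.0, abs=1e-9)

    def test_z_shift_absorbed_by_dta(self):
        # steep-gradient synthetic cube shifted by 2.5 mm in z: inside the
        # 3-mm DTA every point still agrees (gamma <= 2.5/3), while at
        # 2%/2mm the shift exceeds the DTA and gradient regions fail
        nz = 40
        z = np.arange(nz) * 1.0
        profile = 1.0 / (1.0 + np.exp((z - 20.0) / 2.0)) + 0.15
        dose = np.broadcast_to(profile, (20, 20, nz)).copy()
        cube = DoseCube(dose=dose, spacing=[1.0] * 3, origin=[0, 0, 0.0],
                        engine_tag="apb")
        shifted = DoseCube(dose=dose, spacing=[1.0] * 3, origin=[0, 0, 2.5],
                           engine_tag="apb")
        pts = np.stack(np.meshgrid(cube.axis_centers(0)[5:15],
                                   cube.axis_centers(1)[5:15],
                                   np.arange(12.0, 30.0, 2.0),
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        vals = cube.interp_points(pts)
        res3 = gamma_3d(pts, vals, shifted, GammaCriterion(3.0, 3.0, 10.0))
        assert res3.pass_rate == 100.0
        res2 = gamma_3d(pts, vals, shifted, GammaCriterion(2.0, 2.0, 10.0))
        assert res2.pass_rate < 100.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        cube = self._cube(rng, n=10)
        pts = rng.uniform(4.0, 14.0, size=(40, 3))
        vals = np.clip(cube.interp_points(pts)
                       + 0.2 * rng.standard_normal(40), 0.0, None)
        crit = GammaCriterion(3.0, 3.0, 10.0)
        res = gamma_3d(pts, vals, cube, crit)

        # brute force over the same offset sphere
        from protonval.gamma import _sphere_offsets
        offs, r2 = _sphere_offsets(crit.dta_mm)
        norm = cube.max_dose()
        dd = crit.dose_percent / 100.0 * norm
        sel = vals >= crit.threshold_percent / 100.0 * norm
        gammas = []
        for p, v in zip(pts[sel], vals[sel]):
            cand = p[None, :] + offs
            dose = cube.interp_points(cand)
            inside = np.all((cand >= cube.origin - 1e-12)
                            & (cand <= cube.origin
                               + (np.array(cube.shape) - 1) * cube.spacing
                               + 1e-12), axis=1)
            g2 = ((dose[inside] - v) / dd) ** 2 + r2[inside] / crit.dta_mm ** 2
            gammas.append(np.sqrt(g2.min()))
        mean_oracle = float(np.mean(gammas))
        pass_oracle = float(100.0 * np.mean(np.array(gammas) <= 1.0 + 1e-12))
        assert res.mean_gamma == pytest.approx(mean_oracle, abs=1e-9)
        assert res.pass_rate == pytest.approx(pass_oracle, abs=1e-9)


class TestExtractPlane:
    def _linear_cube(self):
        nx, ny, nz = 12, 12, 30
        z = np.arange(nz) * 2.0
        dose = np.broadcast_to(0.1 + z / 60.0, (nx, ny, nz)).copy()
        return DoseCube(dose=dose, spacing=[2.0] * 3,
                        origin=[-11.0, -11.0, 1.0], engine_tag="apb")

    def test_on_slice_identity(self):
        cube = self._linear_cube()
        lattice = cube.axis_centers(0)[2:-2]
        # depth measured from the cube front face; voxel center k=3 sits at
        # front + (3 + 0.5) * spacing
        plane = extract_plane(cube, 7.0, lattice, lattice)
        np.testing.assert_allclose(plane, cube.dose[2:-2, 2:-2, 3], rtol=1e-12)

    def test_linear_in_depth(self):
        cube = self._linear_cube()
        lattice = cube.axis_centers(0)[2:-2]
        a = extract_plane(cube, 10.0, lattice, lattice)
        b = extract_plane(cube, 12.0, lattice, lattice)
        mid = extract_plane(cube, 11.0, lattice, lattice)
        np.testing.assert_allclose(mid, 0.5 * (a + b), rtol=1e-12)

    def test_values_bounded_by_neighbors(self):
        rng = np.random.default_rng(8)
        dose = rng.random((10, 10, 10))
        cube = DoseCube(dose=dose, spacing=[2.0] * 3, origin=[0, 0, 0],
                        engine_tag="apb")
        fine = np.arange(2.0, 16.0, 0.5)
        plane = extract_plane(cube, 9.3, fine, fine)
        assert plane.max() <= dose.max() + 1e-12
        assert plane.min() >= dose.min() - 1e-12

    def test_outside_depth_rejected(self):
        cube = self._linear_cube()
        with pytest.raises(ValueError):
            extract_plane(cube, 100.0, cube.axis_centers(0),
                          cube.axis_centers(1))


class TestDepthSearch:
    def _gradient_cube(self, range_shift=0.0):
        # dose with smooth lateral structure and a distal falloff; a
        # positive `range_shift` moves the falloff deeper within the same
        # cube frame (emulating a range error of the evaluated engine)
        nx, ny, nz = 30, 30, 60
        x = np.arange(nx) * 2.0 - 29.0
        z = np.arange(nz) * 1.0
        lateral = np.exp(-x ** 2 / (2 * 18.0 ** 2))
        depth = 1.0 / (1.0 + np.exp((z - 40.0 - range_shift) / 2.5)) + 0.2
        dose = lateral[:, None, None] * lateral[None, :, None] \
            * depth[None, None, :]
        return DoseCube(dose=dose, spacing=[2.0, 2.0, 1.0],
                        origin=[-29.0, -29.0, 0.5],
                        engine_tag="apb")

    def test_self_consistent_depth_recovered(self):
        cube = self._gradient_cube()
        d_e = 30.0
        lat = np.arange(-20.0, 20.1, 2.0)
        ref = extract_plane(cube, d_e, lat, lat)
        res = depth_search(ref, (lat[0], lat[0]), 2.0, cube, d_e=d_e,
                           d_m=10.0, criterion=GammaCriterion(2.0, 2.0, 5.0),
                           step_mm=0.1)
        assert res.d_gamma == pytest.approx(d_e, abs=0.1 + 1e-9)
        assert res.delta == pytest.approx(0.0, abs=0.1 + 1e-9)

    @pytest.mark.parametrize("shift", [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    def test_known_shift_recovered(self, shift):
        cube = self._gradient_cube()
        shifted = self._gradient_cube(range_shift=shift)
        d_e = 30.0
        lat = np.arange(-20.0, 20.1, 2.0)
        ref = extract_plane(cube, d_e, lat, lat)
        res = depth_search(ref, (lat[0], lat[0]), 2.0, shifted, d_e=d_e,
                           d_m=10.0, criterion=GammaCriterion(2.0, 2.0, 5.0),
                           step_mm=0.1)
        # dose shifted deeper by `shift` puts best agreement at d_e + shift
        assert abs(res.delta) == pytest.approx(abs(shift), abs=0.1 + 1e-9)
        assert res.delta == pytest.approx(-shift, abs=0.1 + 1e-9)

    def test_window_truncation_warns(self):
        cube = self._gradient_cube()
        lat = np.arange(-20.0, 20.1, 2.0)
        ref = extract_plane(cube, 3.0, lat, lat)
        with pytest.warns(UserWarning, match="truncated"):
            depth_search(ref, (lat[0], lat[0]), 2.0, cube, d_e=3.0, d_m=3.0,
                         criterion=GammaCriterion(3.0, 3.0, 5.0),
                         window_mm=5.0, step_mm=0.5)


class TestResamplePlane:
    def test_preserves_values_at_nodes(self):
        rng = np.random.default_rng(9)
        vals = rng.random((8, 6))
        out, origin, sp = resample_plane(vals, (-28.0, -17.5), 7.0, 3.5)
        assert sp == 3.5
        np.testing.assert_allclose(out[::2, ::2], vals, rtol=1e-12)
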