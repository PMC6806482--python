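"""Analytical pencil-beam (APB) dose engine.

Each spot is computed as the product of two factors evaluated under the
infinite-slab approximation:

* the integrated depth dose (IDD) of the pencil, looked up at the
  water-equivalent depth accumulated **along the spot's central axis only**;
* a lateral 2D Gaussian whose variance grows with depth following a
  Fermi-Eyges accumulation of Highland scattering power along that same axis.

The slab approximation is the engine's defining limitation: material off the
central axis is invisible, so a spot whose axis misses a heterogeneity is
computed exactly as in homogeneous water.  Summing all weighted spots gives
the total dose in Gy.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

from . import physics
from .beamline import PBSPlan, Beam, beam_frame
from .dose import DoseCube
from .idd import IDDLibrary
from .phantom import VoxelPhantom, _trace_wed_kernel

logger = logging.getLogger(__name__)

_E_MIN_SCATTER = 3.0    # MeV floor for scattering-power evaluation


def _axis_profiles(rsp, x0g, spacing, lo, hi, entry, direction, z_rel,
                   nominal_energy, beamline):
    """WED, residual energy and Fermi-Eyges sigma^2 along one spot axis.

    ``z_rel`` are geometric depths (mm) along the axis measured from ``entry``.
    Scattering power uses the local material radiation length; the IDD index
    is the range-shifter WET plus the accumulated phantom WED.
    """
    z_rel = np.ascontiguousarray(z_rel, dtype=float)
    wed = np.empty_like(z_rel)
    hit = _trace_wed_kernel(rsp, spacing, lo, hi,
                            np.asarray(entry, dtype=float),
                            np.asarray(direction, dtype=float), z_rel, wed)
    # residual energy at each depth (after range shifter + phantom WED)
    r0 = physics.range_from_energy(nominal_energy)
    res = np.clip(r0 - beamline.range_shifter_wet - wed, 0.05, None)
    e_res = physics.energy_from_range(res)
    # local radiation length along the axis (nearest-voxel sample)
    pts = np.asarray(entry, dtype=float)[None, :] + \
        z_rel[:, None] * np.asarray(direction, dtype=float)[None, :]
    idx = np.clip(np.rint((pts - (lo + spacing / 2.0)) / spacing).astype(int),
                  0, np.array(rsp.shape) - 1)
    x0_loc = x0g[idx[:, 0], idx[:, 1], idx[:, 2]]
    # Fermi-Eyges: sigma^2(z) = int T(z') (z - z')^2 dz' via cumulative moments
    t_pow = physics.scattering_power(np.clip(e_res, _E_MIN_SCATTER, None)) \
        * physics.WATER_X0_MM / x0_loc
    dz = np.diff(z_rel, prepend=z_rel[0])
    a0 = np.cumsum(t_pow * dz)
    a1 = np.cumsum(t_pow * z_rel * dz)
    a2 = np.cumsum(t_pow * z_rel ** 2 * dz)
    sigma2_mcs = np.clip(z_rel ** 2 * a0 - 2.0 * z_rel * a1 + a2, 0.0, None)
    return wed, e_res, sigma2_mcs, bool(hit)


@njit(cache=True)
def _deposit_spot(dose, amp, sig2, x_centers, y_centers, x0, y0, nsig):
    nx = x_centers.shape[0]
    ny = y_centers.shape[0]
    nz = amp.shape[0]
    dx = x_centers[1] - x_centers[0] if nx > 1 else 1.0
    dy = y_centers[1] - y_centers[0] if ny > 1 else 1.0
    for k in range(nz):
        a = amp[k]
        if a <= 0.0:
            continue
        s2 = sig2[k]
        norm = a / (2.0 * np.pi * s2)
        halfw = nsig * np.sqrt(s2)
        i0 = int(np.floor((x0 - halfw - x_centers[0]) / dx))
        i1 = int(np.ceil((x0 + halfw - x_centers[0]) / dx)) + 1
        j0 = int(np.floor((y0 - halfw - y_centers[0]) / dy))
        j1 = int(np.ceil((y0 + halfw - y_centers[0]) / dy)) + 1
        if i0 < 0: i0 = 0
        if j0 < 0: j0 = 0
        if i1 > nx: i1 = nx
        if j1 > ny: j1 = ny
        inv2s2 = 0.5 / s2
        for i in range(i0, i1):
            ex = np.exp(-(x_centers[i] - x0) ** 2 * inv2s2)
            for j in range(j0, j1):
                dose[i, j, k] += norm * ex * np.exp(-(y_centers[j] - y0) ** 2 * inv2s2)


def _sub_pencil_offsets(n_sub: int):
    """Offsets (units of sigma_air) and weights for N x N mini-beam splitting."""
    if n_sub <= 1:
        return [(0.0, 0.0, 1.0, 1.0)]
    edges = np.linspace(-2.5, 2.5, n_sub + 1)
    from scipy.stats import norm
    cdf = norm.cdf(edges)
    w1 = np.diff(cdf) / (cdf[-1] - cdf[0])
    centers = 0.5 * (edges[:-1] + edges[1:])
    sub_sigma_frac = (edges[1] - edges[0]) / np.sqrt(12.0)
    out = []
    for cx, wx in zip(centers, w1):
        for cy, wy in zip(centers, w1):
            out.append((cx, cy, wx * wy, sub_sigma_frac))
    return out


def compute_dose_apb(plan: PBSPlan, phantom: VoxelPhantom, grid_spacing: float,
                     idd_library: IDDLibrary | None = None,
                     secondary_halo: bool = True, halo_sigma_mm: float = 15.0,
                     n_sub_pencils: int = 1, n_sigma_window: float = 4.5) -> DoseCube:
    """Compute the APB dose cube for ``plan`` on ``phantom``.

    The dose grid covers the phantom extent at ``grid_spacing`` mm.  Beams
    along +z are computed natively; oblique beams are computed on a
    beam-aligned resampling of the phantom and mapped back (documented
    smoothing of the order of the grid spacing).
    """
    lib = idd_library if idd_library is not None else IDDLibrary()
    grid_spacing = float(grid_spacing)
    # both engines see the same voxelized materials on the dose grid
    phantom = phantom.resampled(grid_spacing)
    lo = phantom.lower_corner()
    extent = np.array(phantom.shape) * phantom.spacing
    shape = np.maximum(np.round(extent / grid_spacing).astype(int), 1)
    origin = lo + grid_spacing / 2.0
    dose = np.zeros(tuple(shape))

    for beam in plan.beams:
        if np.allclose(beam.direction, [0.0, 0.0, 1.0], atol=1e-9):
            _beam_dose_z(dose, origin, grid_spacing, beam, phantom, lib,
                         secondary_halo, halo_sigma_mm,
                         n_sub_pencils, n_sigma_window)
        else:
            _beam_dose_oblique(dose, origin, grid_spacing, beam, phantom, lib,
                               secondary_halo, halo_sigma_mm,
                               n_sub_pencils, n_sigma_window)
    spacing = np.array([grid_spacing] * 3)
    return DoseCube(dose=dose, spacing=spacing, origin=origin, engine_tag="apb")


def _beam_dose_z(dose, origin, gs, beam: Beam, phantom: VoxelPhantom,
                 lib: IDDLibrary, secondary_halo, halo_sigma_mm,
                 n_sub, nsig) -> None:
    rsp = np.ascontiguousarray(phantom.rsp_grid)
    x0g = np.ascontiguousarray(phantom.x0_grid)
    lo = phantom.lower_corner()
    hi = phantom.upper_corner()
    nx, ny, nz = dose.shape
    xc = origin[0] + np.arange(nx) * gs
    yc = origin[1] + np.arange(ny) * gs
    zc = origin[2] + np.arange(nz) * gs
    z_entry = lo[2]
    z_rel = zc - z_entry
    scale = beam.beamline.protons_per_mu * physics.GY_MM2_PER_MEV_PER_MM
    subs = _sub_pencil_offsets(n_sub)

    for layer in beam.layers:
        curve = lib.curve_for_beamline(layer.energy, beam.beamline)
        sigma_air = beam.beamline.spot_sigma_air(layer.energy)
        for spot in layer.spots:
            if spot.weight <= 0:
                continue
            for ox, oy, sw, ssig in subs:
                px = spot.x + ox * sigma_air
                py = spot.y + oy * sigma_air
                entry = np.array([px, py, z_entry - 1e-6])
                wed, e_res, sig2_mcs, hit = _axis_profiles(
                    rsp, x0g, phantom.spacing, lo, hi, entry,
                    np.array([0.0, 0.0, 1.0]), z_rel, layer.energy, beam.beamline)
                if not hit:
                    logger.info("spot axis at (%.1f, %.1f) misses the phantom; "
                                "air transport only", px, py)
                amp_tot = spot.weight * sw * scale * curve.mev_per_mm_at(wed)
                sig2 = (sigma_air * ssig) ** 2 + sig2_mcs
                if secondary_halo:
                    amp_sec = spot.weight * sw * scale \
                        * curve.mev_per_mm_secondary_at(wed)
                    _deposit_spot(dose, amp_tot - amp_sec, sig2,
                                  xc, yc, px, py, nsig)
                    _deposit_spot(dose, amp_sec, sig2 + halo_sigma_mm ** 2,
                                  xc, yc, px, py, nsig)
                else:
                    _deposit_spot(dose, amp_tot, sig2, xc, yc, px, py, nsig)


def _beam_dose_oblique(dose, origin, gs, beam: Beam, phantom: VoxelPhantom,
                       lib, secondary_halo, halo_sigma_mm,
                       n_sub, nsig) -> None:
    """Oblique beam: resample the phantom onto a beam-aligned grid, run the
    +z fast path there, then trilinearly map the dose back."""
    from scipy.ndimage import map_coordinates

    e1, e2, d = beam_frame(beam.direction)
    rot = np.stack([e1, e2, d])            # beam-frame row basis
    lo = phantom.lower_corner()
    hi = phantom.upper_corner()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    bc = corners @ rot.T
    bmin, bmax = bc.min(axis=0), bc.max(axis=0)
    bshape = np.maximum(np.ceil((bmax - bmin) / gs).astype(int), 1)
    borigin = bmin + gs / 2.0

    # sample material index (nearest neighbour) on the beam-aligned grid
    bx = borigin[0] + np.arange(bshape[0]) * gs
    by = borigin[1] + np.arange(bshape[1]) * gs
    bz = borigin[2] + np.arange(bshape[2]) * gs
    bxx, byy, bzz = np.meshgrid(bx, by, bz, indexing="ij")
    pts = np.stack([bxx, byy, bzz], axis=-1) @ rot      # back to lab frame
    idx = (pts - phantom.origin) / phantom.spacing
    mat = map_coordinates(phantom.material_index.astype(np.int16),
                          [idx[..., 0], idx[..., 1], idx[..., 2]],
                          order=0, mode="constant",
                          cval=phantom.materials.index("air"))
    bphantom = VoxelPhantom(mat.astype(np.int16), np.array([gs] * 3),
                            borigin, phantom.materials)

    bdose = np.zeros(tuple(bshape))
    bbeam = Beam(np.array([0.0, 0.0, 1.0]), beam.beamline, beam.layers, beam.name)
    _beam_dose_z(bdose, borigin, gs, bbeam, bphantom, lib,
                 secondary_halo, halo_sigma_mm, n_sub, nsig)

    # map the beam-frame dose back onto the lab grid
    nx, ny, nz = dose.shape
    xc = origin[0] + np.arange(nx) * gs
    yc = origin[1] + np.arange(ny) * gs
    zc = origin[2] + np.arange(nz) * gs
    lxx, lyy, lzz = np.meshgrid(xc, yc, zc, indexing="ij")
    lab_pts = np.stack([lxx, lyy, lzz], axis=-1) @ rot.T
    bidx = (lab_pts - borigin) / gs
    dose += np.clip(map_coordinates(bdose, [bidx[..., 0], bidx[..., 1],
                                            bidx[..., 2]], order=1,
                                    mode="constant", cval=0.0), 0.0, None)


def apb_dose_matrix(phantom: VoxelPhantom, beam: Beam, points: np.ndarray,
                    idd_library: IDDLibrary | None = None,
                    halo_sigma_mm: float = 15.0) -> np.ndarray:
    """Per-unit-weight APB dose of every spot at sample ``points`` (N, 3).

    Used by plan optimization.  Returns a (n_points, n_spots) matrix.
    """
    lib = idd_library if idd_library is not None else IDDLibrary()
    e1, e2, d = beam_frame(beam.direction)
    rsp = np.ascontiguousarray(phantom.rsp_grid)
    x0g = np.ascontiguousarray(phantom.x0_grid)
    lo = phantom.lower_corner()
    hi = phantom.upper_corner()
    pts = np.asarray(points, dtype=float)
    # beam-frame coordinates of the sample points
    pu = pts @ e1
    pv = pts @ e2
    pw = pts @ d
    # entry plane: most upstream corner along d
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    w_entry = float((corners @ d).min())
    z_grid = np.arange(0.0, float((corners @ d).max() - w_entry) + 1.0, 1.0)
    scale = beam.beamline.protons_per_mu * physics.GY_MM2_PER_MEV_PER_MM

    cols = []
    for layer in beam.layers:
        curve = lib.curve_for_beamline(layer.energy, beam.beamline)
        sigma_air = beam.beamline.spot_sigma_air(layer.energy)
        for spot in layer.spots:
            entry = spot.x * e1 + spot.y * e2 + (w_entry - 1e-6) * d
            wed, e_res, sig2_mcs, _ = _axis_profiles(
                rsp, x0g, phantom.spacing, lo, hi, entry, d, z_grid,
                layer.energy, beam.beamline)
            amp_z = scale * curve.mev_per_mm_at(wed)
            sec_z = scale * curve.mev_per_mm_secondary_at(wed)
            zq = pw - w_entry
            amp = np.interp(zq, z_grid, amp_z)
            sec = np.interp(zq, z_grid, sec_z)
            sig2 = sigma_air ** 2 + np.interp(zq, z_grid, sig2_mcs)
            sig2h = sig2 + halo_sigma_mm ** 2
            r2 = (pu - spot.x) ** 2 + (pv - spot.y) ** 2
            cols.append((amp - sec) / (2 * np.pi * sig2) * np.exp(-r2 / (2 * sig2))
                        + sec / (2 * np.pi * sig2h) * np.exp(-r2 / (2 * sig2h)))
    return np.stack(cols, axis=1)
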