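"""Plan construction: SOBP weight optimization, uniform target plans on a
phantom (with water override), and random spot/layer degradation.

All optimization is APB-based: layer/spot weights are found by nonnegative
least squares against a uniform-dose objective computed with the analytical
engine.  The Monte Carlo engine is never used for optimization, mirroring
clinical practice of comparing identical spot lists between engines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from . import physics
from .apb import apb_dose_matrix
from .beamline import Beam, BeamLineConfig, EnergyLayer, PBSPlan, Spot, beam_frame
from .idd import IDDLibrary
from .phantom import VoxelPhantom, wed_at_depths

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference SOBP (calibration-beam style)
# ---------------------------------------------------------------------------

@dataclass
class SOBPResult:
    plan: PBSPlan
    depth_grid: np.ndarray
    central_axis_dose: np.ndarray     # Gy on the central axis (broad field)
    plateau_flatness: float           # max |D - prescription| / prescription
    distal_90_mm: float


def _broad_field_depth_dose(weights_per_area, curves, depth_grid):
    """Central-axis dose (Gy) of a laterally uniform field in water.

    For an infinite uniform spot lattice the lateral Gaussians integrate out,
    leaving dose(z) = sum_l areal_MU_density_l * IDD_l(z).
    """
    d = np.zeros_like(depth_grid)
    for w, c in zip(weights_per_area, curves):
        d += w * c(depth_grid)
    return d


def optimize_sobp(target_range_mm: float = 250.0, modulation_mm: float = 100.0,
                  prescription_gy: float = 2.0,
                  beamline: BeamLineConfig | None = None,
                  field_size_mm: float = 100.0,
                  spot_pitch_mm: float = 7.0,
                  layer_range_step_mm: float = 3.0,
                  idd_library: IDDLibrary | None = None,
                  label: str = "reference-sobp") -> SOBPResult:
    """Weight a stack of pristine peaks into a flat SOBP in water.

    The distal 90% dose point lands at ``target_range_mm`` (within one depth
    bin) and the plateau covers ``modulation_mm`` proximally of it, flat to
    about +-1% for the default layer spacing.  The returned plan carries a
    uniform square spot lattice of ``field_size_mm`` at ``spot_pitch_mm``.
    """
    if modulation_mm > target_range_mm:
        raise ValueError("modulation cannot exceed the target range")
    bl = beamline if beamline is not None else BeamLineConfig(
        range_shifter_wet=0.0, air_gap=0.0)
    lib = idd_library if idd_library is not None else IDDLibrary()

    rs = bl.range_shifter_wet
    # candidate layers: machine energies whose (shifted) range spans the SOBP
    e_grid = np.asarray(bl.available_energies, dtype=float)
    ranges = physics.range_from_energy(e_grid) - rs
    distal_target = float(target_range_mm)

    dz = 1.0
    depth_grid = np.arange(0.0, distal_target + 40.0, dz)

    def build(emax_range: float):
        wanted = np.arange(emax_range, emax_range - modulation_mm - 2.0,
                           -layer_range_step_mm)
        idx = sorted({int(np.argmin(np.abs(ranges - r))) for r in wanted})
        energies = e_grid[idx]
        if len(energies) == 0:
            raise ValueError("no machine energies cover the requested SOBP")
        curves = [lib.curve_for_beamline(e, bl) for e in energies]
        # plateau objective on [R - modulation, R], distal edge included
        plateau = (depth_grid >= distal_target - modulation_mm) & \
                  (depth_grid <= distal_target - 2.0)
        a = np.stack([c(depth_grid[plateau]) for c in curves], axis=1)
        w, res = nnls(a, np.full(plateau.sum(), prescription_gy))
        return energies, curves, w, res

    # iterate: place the deepest layer so the distal 90% lands on target
    emax_range = distal_target
    energies = curves = w = None
    d90 = np.nan
    for _ in range(4):
        energies, curves, w, res = build(emax_range)
        if len(energies) == 1:
            break
        dose = _broad_field_depth_dose(w, curves, depth_grid)
        d90 = _distal_level_depth(depth_grid, dose, 0.9 * prescription_gy)
        err = d90 - distal_target
        if abs(err) < 0.25:
            break
        emax_range -= err

    dose = _broad_field_depth_dose(w, curves, depth_grid)
    plateau = (depth_grid >= distal_target - modulation_mm + 3.0) & \
              (depth_grid <= distal_target - 3.0)
    if len(energies) > 1:
        flat = float(np.max(np.abs(dose[plateau] - prescription_gy))
                     / prescription_gy)
        d90 = _distal_level_depth(depth_grid, dose, 0.9 * prescription_gy)
        if flat > 0.03:
            raise ValueError(f"SOBP infeasible with the available layers: "
                             f"achievable flatness {flat:.1%}")
    else:
        flat = math.nan   # pristine peak: flatness check not applicable
        d90 = _distal_level_depth(depth_grid, dose, 0.9 * float(dose.max()))

    # distribute areal weight density onto the square spot lattice
    half = field_size_mm / 2.0
    coords = np.arange(-half + spot_pitch_mm / 2.0, half, spot_pitch_mm)
    layers = []
    for e, wl in zip(energies, w):
        if wl <= 0:
            continue
        spot_mu = wl * spot_pitch_mm ** 2
        spots = [Spot(float(x), float(y), float(e), float(spot_mu))
                 for x in coords for y in coords]
        layers.append(EnergyLayer(float(e), spots))
    plan = PBSPlan([Beam(np.array([0.0, 0.0, 1.0]), bl, layers, "sobp")], label)
    return SOBPResult(plan, depth_grid, dose, flat, float(d90))


def _distal_level_depth(depth, dose, level) -> float:
    """Deepest crossing of ``dose`` through ``level`` on the distal side."""
    ipk = int(np.argmax(dose))
    tail = dose[ipk:]
    below = np.nonzero(tail < level)[0]
    if below.size == 0:
        return float(depth[-1])
    j = ipk + below[0]
    d0, d1 = dose[j - 1], dose[j]
    if d0 == d1:
        return float(depth[j])
    return float(depth[j - 1] + (d0 - level) / (d0 - d1)
                 * (depth[j] - depth[j - 1]))


# ---------------------------------------------------------------------------
# uniform target plans on a phantom
# ---------------------------------------------------------------------------

def override_heterogeneities_to_water(phantom: VoxelPhantom,
                                      open_axes=(0,)) -> VoxelPhantom:
    """Copy of the phantom with internal heterogeneities overridden to water.

    Every voxel that is not air becomes water, and air pockets that do not
    reach the outside become water too, so the override removes exactly the
    discrete internal heterogeneities while keeping the external contour.
    ``open_axes`` lists axes whose boundary faces do *not* count as outside:
    anatomical channels extruded along such an axis (an airway running the
    length of a neck section) are still treated as internal cavities.
    """
    from scipy.ndimage import label

    air_idx = phantom.materials.index("air")
    water_idx = phantom.materials.index("water")
    mat = phantom.material_index.copy()
    body = mat != air_idx
    mat[body] = water_idx
    air_mask = ~body
    labels, n = label(air_mask)
    if n > 0:
        border = set()
        for axis in range(3):
            if axis in open_axes:
                continue
            sl0 = [slice(None)] * 3; sl0[axis] = 0
            sl1 = [slice(None)] * 3; sl1[axis] = -1
            border |= set(np.unique(labels[tuple(sl0)]))
            border |= set(np.unique(labels[tuple(sl1)]))
        border.discard(0)
        enclosed = np.isin(labels, [i for i in range(1, n + 1)
                                    if i not in border])
        mat[enclosed] = water_idx
    return VoxelPhantom(mat, phantom.spacing.copy(), phantom.origin.copy(),
                        phantom.materials, phantom.hu)


def create_uniform_plan(phantom: VoxelPhantom, target_box,
                        beam_direction=(0.0, 0.0, 1.0),
                        beamline: BeamLineConfig | None = None,
                        override_to_water: bool = True,
                        prescription_gy: float = 2.0,
                        spot_pitch_factor: float = 0.85,
                        lateral_margin_mm: float = 7.0,
                        layer_range_step_mm: float = 2.5,
                        distal_margin_mm: float = 2.0,
                        sample_spacing_mm: float = 4.0,
                        uniformity_tolerance: float = 0.03,
                        idd_library: IDDLibrary | None = None,
                        label: str = "uniform") -> PBSPlan:
    """APB-optimized plan delivering a uniform dose to ``target_box``.

    ``target_box`` is ((x0, x1), (y0, y1), (z0, z1)) in mm.  With
    ``override_to_water`` the optimization runs on a copy of the phantom
    whose internal heterogeneities are overridden to water (recalculating the
    returned plan on the true phantom then yields the deliberately nonuniform
    distributions used for engine stress-testing).
    """
    bl = beamline if beamline is not None else BeamLineConfig()
    lib = idd_library if idd_library is not None else IDDLibrary()
    box = np.asarray(target_box, dtype=float)
    lo_ph = phantom.lower_corner()
    hi_ph = phantom.upper_corner()
    if np.any(box[:, 0] < lo_ph) or np.any(box[:, 1] > hi_ph):
        raise ValueError("target box extends outside the phantom")

    opt_phantom = override_heterogeneities_to_water(phantom) \
        if override_to_water else phantom
    e1, e2, d = beam_frame(beam_direction)

    # target-box corners in the beam frame set the lateral lattice and depths
    corners = np.array([[x, y, z] for x in box[0] for y in box[1] for z in box[2]])
    cu, cv, cw = corners @ e1, corners @ e2, corners @ d
    ph_corners = np.array([[x, y, z] for x in (lo_ph[0], hi_ph[0])
                           for y in (lo_ph[1], hi_ph[1])
                           for z in (lo_ph[2], hi_ph[2])])
    w_entry = float((ph_corners @ d).min())

    # WED of the proximal/distal box faces along the central ray
    center_uv = np.array([cu.mean(), cv.mean()])
    entry = center_uv[0] * e1 + center_uv[1] * e2 + (w_entry - 1e-6) * d
    depths = np.array([cw.min() - w_entry, cw.max() - w_entry])
    wed_pd = wed_at_depths(opt_phantom, entry, d, depths)
    wed_prox, wed_dist = float(wed_pd[0]), float(wed_pd[1])

    rs = bl.range_shifter_wet
    e_grid = np.asarray(bl.available_energies, dtype=float)
    ranges = physics.range_from_energy(e_grid) - rs
    wanted = np.arange(wed_dist + distal_margin_mm, wed_prox - 1.0,
                       -layer_range_step_mm)
    if wanted.size == 0:
        wanted = np.array([wed_dist + distal_margin_mm])
    idx = sorted({int(np.argmin(np.abs(ranges - r))) for r in wanted})
    energies = e_grid[idx]

    sigma_ref = bl.spot_sigma_air(float(energies[-1]))
    pitch = spot_pitch_factor * sigma_ref
    nu = int(np.ceil((cu.max() - cu.min() + 2 * lateral_margin_mm) / pitch))
    nv = int(np.ceil((cv.max() - cv.min() + 2 * lateral_margin_mm) / pitch))
    su = cu.mean() + (np.arange(nu) - (nu - 1) / 2.0) * pitch
    sv = cv.mean() + (np.arange(nv) - (nv - 1) / 2.0) * pitch

    layers = [EnergyLayer(float(e), [Spot(float(x), float(y), float(e), 1.0)
                                     for x in su for y in sv])
              for e in energies]
    beam = Beam(d, bl, layers, label)

    # optimization sample points inside the box, excluding air voxels so an
    # irregular target crossing a curved surface is handled naturally
    axes = [np.arange(a0 + sample_spacing_mm / 2.0, a1, sample_spacing_mm)
            for a0, a1 in box]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    idxp = np.clip(np.rint((points - opt_phantom.origin)
                           / opt_phantom.spacing).astype(int),
                   0, np.array(opt_phantom.shape) - 1)
    mat_at = opt_phantom.material_index[idxp[:, 0], idxp[:, 1], idxp[:, 2]]
    in_body = mat_at != opt_phantom.materials.index("air")
    if not np.any(in_body):
        raise ValueError("target box contains no non-air voxels")
    points = points[in_body]

    a = apb_dose_matrix(opt_phantom, beam, points, lib)
    # Tikhonov-augmented NNLS: the ridge term spreads weight over neighboring
    # spots instead of the sparse spikes plain NNLS favors, smoothing the
    # delivered dose at a negligible cost in residual
    lam = 0.02 * float(np.mean(np.sum(a * a, axis=0)))
    a_aug = np.vstack([a, np.sqrt(lam) * np.eye(a.shape[1])])
    b_aug = np.concatenate([np.full(points.shape[0], prescription_gy),
                            np.zeros(a.shape[1])])
    w, res = nnls(a_aug, b_aug, maxiter=10 * a.shape[1])
    achieved = a @ w
    spread = float(np.max(np.abs(achieved - prescription_gy)) / prescription_gy)
    if override_to_water and spread > uniformity_tolerance:
        logger.warning("override-phantom target uniformity %.1f%% exceeds the "
                       "%.1f%% tolerance", 100 * spread,
                       100 * uniformity_tolerance)

    # place optimized weights back on the spot list, dropping zero spots
    out_layers = []
    k = 0
    for layer in beam.layers:
        spots = []
        for s in layer.spots:
            if w[k] > 1e-9:
                spots.append(Spot(s.x, s.y, s.energy, float(w[k])))
            k += 1
        if spots:
            out_layers.append(EnergyLayer(layer.energy, spots))
    if not out_layers:
        raise ValueError(f"optimizer converged to an empty plan "
                         f"(residual {res:.3g})")
    plan = PBSPlan([Beam(d, bl, out_layers, label)], label)
    plan.target_uniformity = spread
    return plan


# ---------------------------------------------------------------------------
# plan degradation
# ---------------------------------------------------------------------------

def degrade_plan(plan: PBSPlan, mode: str, fraction: float, seed: int) -> PBSPlan:
    """Copy of ``plan`` with ceil(fraction * N) random spots or layers removed.

    Removal is uniform at random under ``seed``; the original is untouched.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if mode not in ("spots", "layers"):
        raise ValueError("mode must be 'spots' or 'layers'")

    if mode == "spots":
        n = plan.n_spots
        n_remove = math.ceil(fraction * n)
        if n_remove >= n:
            raise ValueError("removal would empty the plan")
        removed = set(rng.choice(n, size=n_remove, replace=False).tolist())
        beams = []
        k = 0
        for b in plan.beams:
            layers = []
            for l in b.layers:
                spots = []
                for s in l.spots:
                    if k not in removed:
                        spots.append(Spot(s.x, s.y, s.energy, s.weight))
                    k += 1
                if spots:
                    layers.append(EnergyLayer(l.energy, spots))
            if layers:
                beams.append(Beam(b.direction.copy(), b.beamline, layers, b.name))
        if not beams:
            raise ValueError("removal would empty the plan")
        return PBSPlan(beams, plan.label + f"-deg-spots{fraction}")

    n_layers = sum(len(b.layers) for b in plan.beams)
    n_remove = math.ceil(fraction * n_layers)
    if n_remove >= n_layers:
        raise ValueError("removal would empty the plan")
    removed = set(rng.choice(n_layers, size=n_remove, replace=False).tolist())
    beams = []
    k = 0
    for b in plan.beams:
        layers = []
        for l in b.layers:
            if k not in removed:
                layers.append(EnergyLayer(l.energy,
                                          [Spot(s.x, s.y, s.energy, s.weight)
                                           for s in l.spots]))
            k += 1
        if layers:
            beams.append(Beam(b.direction.copy(), b.beamline, layers, b.name))
    if not beams:
        raise ValueError("removal would empty the plan")
    return PBSPlan(beams, plan.label + f"-deg-layers{fraction}")
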