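"""2D/3D global gamma-index analysis and the depth-of-best-agreement search.

The gamma index combines a dose-difference criterion (percent of a global
normalization dose) with a distance-to-agreement (DTA) criterion:

    gamma(r_ref) = min over r_eval of sqrt( (dD / (p% * D_norm))^2
                                          + (|r_eval - r_ref| / dta)^2 )

A reference point passes when gamma <= 1.  Analyses here are *global* and
absolute: the normalization is the maximum of the computed (evaluation)
dose, no prior rescaling of either distribution, and reference points below
a threshold fraction of the normalization are excluded.  Roles follow QA
practice for planar detector measurements: in 2D the measured plane
(interpolated to a 2 mm grid) is the reference and the computed plane the
evaluation; in 3D the sparse measured points are the reference against the
computed dose cube.

The evaluation distribution is linearly interpolated onto a subgrid of
dta/10 and searched within a radius of 3 x dta; offsets are scanned in
order of increasing distance with early exit, which makes the fast path
exactly equal to a brute-force search over the same subgrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

SEARCH_RADIUS_FACTOR = 3.0
SUBSAMPLE_FACTOR = 10.0      # evaluation subgrid is about dta / SUBSAMPLE_FACTOR


def subgrid_spacing(eval_spacing: float, dta_mm: float) -> float:
    """Fine-grid spacing: the largest divisor of the evaluation spacing not
    exceeding dta / SUBSAMPLE_FACTOR, so evaluation nodes lie exactly on the
    subgrid (an identical plane then yields gamma = 0 identically)."""
    n = max(int(np.ceil(eval_spacing / (dta_mm / SUBSAMPLE_FACTOR))), 1)
    return eval_spacing / n


@dataclass(frozen=True)
class GammaCriterion:
    dose_percent: float              # % of the normalization dose
    dta_mm: float                    # distance to agreement
    threshold_percent: float = 5.0   # reference points below this % excluded

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_percent and dta_mm must be positive")
        if not 0 <= self.threshold_percent < 100:
            raise ValueError("threshold_percent must be in [0, 100)")

    @property
    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta_mm:g}mm"


#: the criteria set used throughout the validation studies
CRITERIA_2MM2 = GammaCriterion(2.0, 2.0)
CRITERIA_3MM3 = GammaCriterion(3.0, 3.0)
CRITERIA_5MM3 = GammaCriterion(5.0, 3.0)
STANDARD_CRITERIA = (CRITERIA_2MM2, CRITERIA_3MM3, CRITERIA_5MM3)


@dataclass
class GammaResult:
    pass_rate: float                 # % of included reference points, gamma <= 1
    mean_gamma: float
    n_included: int
    criterion: GammaCriterion
    roles: str = "reference=measured, evaluation=computed"
    gamma_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_included <= 0:
            raise ValueError("empty analysis: no reference points above threshold")


@dataclass
class DepthSearchResult:
    d_m: float                       # physical measurement depth below surface
    d_e: float                       # expected depth in the dose cube
    d_gamma: float                   # depth of best agreement
    criterion: GammaCriterion
    depths: np.ndarray = field(repr=False)
    pass_rates: np.ndarray = field(repr=False)
    mean_gammas: np.ndarray = field(repr=False)

    @property
    def delta(self) -> float:
        """d_e - d_gamma (mm)."""
        return self.d_e - self.d_gamma


# ---------------------------------------------------------------------------
# plane extraction and resampling
# ---------------------------------------------------------------------------

def extract_plane(cube, depth_mm: float, x_lattice, y_lattice) -> np.ndarray:
    """Computed 2D dose plane at a depth (mm from the cube's front face).

    Bilinear in-plane, linear in depth.  ``x_lattice``/``y_lattice`` are the
    lattice coordinates (mm) on which the plane is sampled.
    """
    z_front = cube.origin[2] - cube.spacing[2] / 2.0
    z = z_front + float(depth_mm)
    z_min = cube.origin[2] - cube.spacing[2] / 2.0
    z_max = z_min + cube.shape[2] * cube.spacing[2]
    if not (z_min <= z <= z_max):
        raise ValueError(f"depth {depth_mm} mm outside the cube z-extent "
                         f"[0, {z_max - z_min:.1f}] mm")
    xx, yy = np.meshgrid(np.asarray(x_lattice, float),
                         np.asarray(y_lattice, float), indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
    return cube.interp_points(pts).reshape(xx.shape)


def resample_plane(values: np.ndarray, origin, pitch: float,
                   target_spacing: float = 2.0):
    """Bilinear interpolation of a detector-pitch plane onto a finer grid.

    Returns (values, origin, spacing) of the resampled plane; the target
    lattice spans the original extent.
    """
    from scipy.interpolate import RegularGridInterpolator
    nx, ny = values.shape
    x = origin[0] + np.arange(nx) * pitch
    y = origin[1] + np.arange(ny) * pitch
    interp = RegularGridInterpolator((x, y), values, method="linear")
    xt = np.arange(x[0], x[-1] + 1e-9, target_spacing)
    yt = np.arange(y[0], y[-1] + 1e-9, target_spacing)
    xx, yy = np.meshgrid(xt, yt, indexing="ij")
    out = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(xx.shape)
    return out, np.array([xt[0], yt[0]]), target_spacing


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _g2_probe(fine, nfx, nfy, i, j, fx, fy, rv, sub, rmax2, inv_dd2,
              inv_dta2, best):
    if i < 0 or i >= nfx or j < 0 or j >= nfy:
        return best
    r2 = ((i - fx) ** 2 + (j - fy) ** 2) * sub * sub
    if r2 > rmax2:
        return best
    diff = fine[i, j] - rv
    g2 = diff * diff * inv_dd2 + r2 * inv_dta2
    return g2 if g2 < best else best


@njit(cache=True)
def _gamma_2d_kernel(ref_vals, ref_fx, ref_fy, fine, dd_abs, dta, sub,
                     out_gamma):
    """Minimum gamma per reference point over the fine evaluation grid.

    ``ref_fx/ref_fy`` are the reference positions in fine-grid units
    (floats; the reference lattice need not be commensurate with the
    subgrid).  Nodes are scanned in square rings around the nearest node
    with early exit once the pure distance term alone exceeds the current
    minimum.
    """
    nfx, nfy = fine.shape
    rmax = SEARCH_RADIUS_FACTOR * dta
    rmax2 = rmax * rmax
    kmax = int(rmax / sub) + 2
    inv_dd2 = 1.0 / (dd_abs * dd_abs)
    inv_dta2 = 1.0 / (dta * dta)
    for p in range(ref_vals.shape[0]):
        fx = ref_fx[p]
        fy = ref_fy[p]
        i0 = int(np.floor(fx + 0.5))
        j0 = int(np.floor(fy + 0.5))
        rv = ref_vals[p]
        best = 1.0e30
        for shell in range(kmax + 1):
            # a ring at L-inf distance `shell` from the nearest node is at
            # least (shell - 1) subgrid cells from the reference point
            if shell > 1:
                dmin2 = ((shell - 1) * sub) ** 2 * inv_dta2
                if dmin2 >= best:
                    break
            if shell == 0:
                best = _g2_probe(fine, nfx, nfy, i0, j0, fx, fy, rv, sub,
                                 rmax2, inv_dd2, inv_dta2, best)
                continue
            for di in range(-shell, shell + 1):
                if di == -shell or di == shell:
                    for dj in range(-shell, shell + 1):
                        best = _g2_probe(fine, nfx, nfy, i0 + di, j0 + dj,
                                         fx, fy, rv, sub, rmax2, inv_dd2,
                                         inv_dta2, best)
                else:
                    best = _g2_probe(fine, nfx, nfy, i0 + di, j0 - shell,
                                     fx, fy, rv, sub, rmax2, inv_dd2,
                                     inv_dta2, best)
                    best = _g2_probe(fine, nfx, nfy, i0 + di, j0 + shell,
                                     fx, fy, rv, sub, rmax2, inv_dd2,
                                     inv_dta2, best)
        out_gamma[p] = np.sqrt(best)


@njit(cache=True)
def _gamma_3d_kernel(ref_vals, ref_pos, cube, lo, sp, offs, off_r2,
                     dd_abs, dta, out_gamma):
    """3D gamma by trilinear interpolation at offsets sorted by radius."""
    nx, ny, nz = cube.shape
    inv_dd2 = 1.0 / (dd_abs * dd_abs)
    inv_dta2 = 1.0 / (dta * dta)
    for p in range(ref_vals.shape[0]):
        rx = ref_pos[p, 0]; ry = ref_pos[p, 1]; rz = ref_pos[p, 2]
        rv = ref_vals[p]
        best = 1.0e30
        for q in range(offs.shape[0]):
            d2 = off_r2[q] * inv_dta2
            if d2 >= best:
                break
            gx = (rx + offs[q, 0] - lo[0]) / sp[0]
            gy = (ry + offs[q, 1] - lo[1]) / sp[1]
            gz = (rz + offs[q, 2] - lo[2]) / sp[2]
            if gx < 0 or gy < 0 or gz < 0 or gx > nx - 1 or gy > ny - 1 \
                    or gz > nz - 1:
                continue
            i = int(gx); j = int(gy); k = int(gz)
            if i > nx - 2: i = nx - 2
            if j > ny - 2: j = ny - 2
            if k > nz - 2: k = nz - 2
            fx = gx - i; fy = gy - j; fz = gz - k
            c00 = cube[i, j, k] * (1 - fx) + cube[i + 1, j, k] * fx
            c10 = cube[i, j + 1, k] * (1 - fx) + cube[i + 1, j + 1, k] * fx
            c01 = cube[i, j, k + 1] * (1 - fx) + cube[i + 1, j, k + 1] * fx
            c11 = cube[i, j + 1, k + 1] * (1 - fx) + cube[i + 1, j + 1, k + 1] * fx
            val = (c00 * (1 - fy) + c10 * fy) * (1 - fz) \
                + (c01 * (1 - fy) + c11 * fy) * fz
            diff = val - rv
            g2 = diff * diff * inv_dd2 + d2
            if g2 < best:
                best = g2
        out_gamma[p] = np.sqrt(best)


# ---------------------------------------------------------------------------
# public analyses
# ---------------------------------------------------------------------------

def gamma_2d(ref_values: np.ndarray, ref_origin, ref_spacing: float,
             eval_values: np.ndarray, eval_origin, eval_spacing: float,
             criterion: GammaCriterion,
             normalization_dose: float | None = None) -> GammaResult:
    """Global 2D gamma with the measured plane as reference.

    Both planes are (nx, ny) arrays with lattice ``origin`` (x0, y0) and
    isotropic ``spacing``; the reference should already be on its analysis
    grid (detector planes are first interpolated to 2 mm).
    """
    ref_values = np.asarray(ref_values, dtype=float)
    eval_values = np.asarray(eval_values, dtype=float)
    norm = float(eval_values.max()) if normalization_dose is None \
        else float(normalization_dose)
    if norm <= 0:
        raise ValueError("normalization dose must be positive")
    dd_abs = criterion.dose_percent / 100.0 * norm
    sub = subgrid_spacing(float(eval_spacing), criterion.dta_mm)

    # fine evaluation grid (linear interpolation)
    from scipy.interpolate import RegularGridInterpolator
    ex = eval_origin[0] + np.arange(eval_values.shape[0]) * eval_spacing
    ey = eval_origin[1] + np.arange(eval_values.shape[1]) * eval_spacing
    interp = RegularGridInterpolator((ex, ey), eval_values, method="linear",
                                     bounds_error=False, fill_value=0.0)
    fx = np.arange(ex[0], ex[-1] + 1e-9, sub)
    fy = np.arange(ey[0], ey[-1] + 1e-9, sub)
    fxx, fyy = np.meshgrid(fx, fy, indexing="ij")
    fine = interp(np.stack([fxx.ravel(), fyy.ravel()], axis=1)).reshape(fxx.shape)

    # included reference points and their indices on the fine grid
    rx = ref_origin[0] + np.arange(ref_values.shape[0]) * ref_spacing
    ry = ref_origin[1] + np.arange(ref_values.shape[1]) * ref_spacing
    rxx, ryy = np.meshgrid(rx, ry, indexing="ij")
    mask = ref_values >= criterion.threshold_percent / 100.0 * norm
    if not np.any(mask):
        raise ValueError("empty analysis: all reference points below threshold")
    pix = (rxx[mask] - fx[0]) / sub
    piy = (ryy[mask] - fy[0]) / sub
    vals = ref_values[mask]

    out = np.empty(vals.size)
    _gamma_2d_kernel(vals, pix, piy, np.ascontiguousarray(fine),
                     dd_abs, criterion.dta_mm, sub, out)
    if np.any(out > 1e14):
        import warnings
        warnings.warn("reference points beyond the evaluation extent have "
                      "no gamma candidates; extend the evaluation lattice",
                      stacklevel=2)
        out[out > 1e14] = np.inf
    gmap = np.full(ref_values.shape, np.nan)
    gmap[mask] = out
    return GammaResult(pass_rate=float(100.0 * np.mean(out <= 1.0 + 1e-12)),
                       mean_gamma=float(out.mean()), n_included=int(vals.size),
                       criterion=criterion, gamma_map=gmap)


def _sphere_offsets(dta: float):
    sub = dta / SUBSAMPLE_FACTOR
    rmax = SEARCH_RADIUS_FACTOR * dta
    k = int(rmax / sub)
    ax = np.arange(-k, k + 1) * sub
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r2 = np.sum(offs ** 2, axis=1)
    keep = r2 <= rmax ** 2
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return np.ascontiguousarray(offs[order]), np.ascontiguousarray(r2[order])


def gamma_3d(ref_points: np.ndarray, ref_values: np.ndarray, cube,
             criterion: GammaCriterion,
             normalization_dose: float | None = None) -> GammaResult:
    """Global 3D gamma: sparse measured points (reference) vs the dose cube.

    ``ref_points`` are (N, 3) mm positions.  Points outside the cube (with a
    DTA margin) are excluded and counted in the result's ``roles`` note.
    The threshold default for 3D analyses is 10 %.
    """
    ref_points = np.asarray(ref_points, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    norm = float(cube.dose.max()) if normalization_dose is None \
        else float(normalization_dose)
    if norm <= 0:
        raise ValueError("normalization dose must be positive")
    dd_abs = criterion.dose_percent / 100.0 * norm

    lo = cube.origin.astype(float)
    hi = cube.origin + (np.array(cube.shape) - 1) * cube.spacing
    inside = np.all((ref_points >= lo - criterion.dta_mm)
                    & (ref_points <= hi + criterion.dta_mm), axis=1)
    above = ref_values >= criterion.threshold_percent / 100.0 * norm
    sel = inside & above
    n_excluded_outside = int(np.sum(above & ~inside))
    if not np.any(sel):
        raise ValueError("empty analysis: no reference points above threshold "
                         "inside the cube")
    offs, r2 = _sphere_offsets(criterion.dta_mm)
    out = np.empty(int(sel.sum()))
    _gamma_3d_kernel(ref_values[sel], np.ascontiguousarray(ref_points[sel]),
                     np.ascontiguousarray(cube.dose), lo,
                     cube.spacing.astype(float), offs, r2, dd_abs,
                     criterion.dta_mm, out)
    roles = "reference=measured points, evaluation=computed cube"
    if n_excluded_outside:
        roles += f" ({n_excluded_outside} points outside cube excluded)"
    return GammaResult(pass_rate=float(100.0 * np.mean(out <= 1.0 + 1e-12)),
                       mean_gamma=float(out.mean()), n_included=int(out.size),
                       criterion=criterion, roles=roles)


def depth_search(ref_values: np.ndarray, ref_origin, ref_spacing: float,
                 cube, d_e: float, d_m: float,
                 criterion: GammaCriterion,
                 window_mm: float = 5.0, step_mm: float = 0.1,
                 eval_margin_mm: float | None = None) -> DepthSearchResult:
    """Depth of best 2D gamma agreement, d_gamma.

    Evaluation planes are extracted from the cube at depths d_e +- window
    (mm from the cube front face) and compared against the fixed reference
    plane.  Best agreement maximizes the pass rate at ``criterion``,
    tie-broken by minimal mean gamma, then by depth closest to d_e.  The
    normalization dose is the maximum of the evaluation plane extracted at
    d_e, held fixed across the scan so the trace is comparable.
    """
    import warnings as _warnings

    z_extent = cube.shape[2] * cube.spacing[2]
    lo_d = max(d_e - window_mm, 0.0)
    hi_d = min(d_e + window_mm, z_extent)
    if lo_d > d_e - window_mm + 1e-9 or hi_d < d_e + window_mm - 1e-9:
        _warnings.warn("depth-search window truncated to the cube extent",
                       stacklevel=2)
    depths = np.arange(lo_d, hi_d + 1e-9, step_mm)

    margin = eval_margin_mm if eval_margin_mm is not None \
        else SEARCH_RADIUS_FACTOR * criterion.dta_mm + ref_spacing
    ex = np.arange(ref_origin[0] - margin,
                   ref_origin[0] + (ref_values.shape[0] - 1) * ref_spacing
                   + margin + 1e-9, ref_spacing)
    ey = np.arange(ref_origin[1] - margin,
                   ref_origin[1] + (ref_values.shape[1] - 1) * ref_spacing
                   + margin + 1e-9, ref_spacing)

    norm = float(extract_plane(cube, d_e, ex, ey).max())
    pass_rates = np.empty(depths.size)
    mean_gammas = np.empty(depths.size)
    for i, d in enumerate(depths):
        plane = extract_plane(cube, float(d), ex, ey)
        res = gamma_2d(ref_values, ref_origin, ref_spacing,
                       plane, (ex[0], ey[0]), ref_spacing, criterion,
                       normalization_dose=norm)
        pass_rates[i] = res.pass_rate
        mean_gammas[i] = res.mean_gamma

    # lexicographic best: max pass rate, min mean gamma, closest to d_e
    order = sorted(range(depths.size),
                   key=lambda i: (-round(pass_rates[i], 9),
                                  round(mean_gammas[i], 12),
                                  abs(depths[i] - d_e)))
    best = order[0]
    return DepthSearchResult(d_m=float(d_m), d_e=float(d_e),
                             d_gamma=float(depths[best]), criterion=criterion,
                             depths=depths, pass_rates=pass_rates,
                             mean_gammas=mean_gammas)
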