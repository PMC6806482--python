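"""Voxel phantoms: container, synthetic builders, and water-equivalent depth.

Coordinate convention (used across the whole package): right-handed, units of
mm, beam travels along +z.  Voxel indices are 0-based; voxel ``i`` along an
axis covers the half-open interval ``[origin + i*d - d/2, origin + i*d + d/2)``
where ``origin`` is the position of the *center* of voxel ``[0, 0, 0]``.

The synthetic builders emulate the bench geometries of a PBS validation
campaign: layered solid-water stacks, a neck analog (soft-tissue cylinder
with a vertebra-like bone annulus enclosing an air channel, cut flat and
resting on solid water), and a water-breast analog on slabs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .materials import MaterialLibrary, MaterialSpec

logger = logging.getLogger(__name__)


@dataclass
class VoxelPhantom:
    material_index: np.ndarray          # int16, shape (nx, ny, nz)
    spacing: np.ndarray                 # mm per axis, shape (3,)
    origin: np.ndarray                  # mm, center of voxel [0,0,0]
    materials: MaterialLibrary
    hu: np.ndarray | None = None        # optional Hounsfield volume

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.material_index.max(initial=0) >= len(self.materials):
            raise ValueError("material_index refers to an undefined material")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def rsp_grid(self) -> np.ndarray:
        return self.materials.rsp_table()[self.material_index]

    @property
    def density_grid(self) -> np.ndarray:
        return self.materials.density_table()[self.material_index]

    @property
    def x0_grid(self) -> np.ndarray:
        return self.materials.x0_table()[self.material_index]

    @property
    def nuclear_grid(self) -> np.ndarray:
        return self.materials.nuclear_table()[self.material_index]

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def lower_corner(self) -> np.ndarray:
        """Position of the outer lower corner of the voxel grid."""
        return self.origin - self.spacing / 2.0

    def upper_corner(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 0.5) * self.spacing

    def material_name_grid_counts(self) -> dict[str, int]:
        counts = np.bincount(self.material_index.ravel(), minlength=len(self.materials))
        return {name: int(c) for name, c in zip(self.materials.names, counts)}

    def resampled(self, spacing: float) -> "VoxelPhantom":
        """Nearest-neighbour resampling of the material grid onto an
        isotropic grid of the given spacing, covering the same extent.

        Both dose engines compute on the resampled grid so that voxelization
        of material boundaries is identical between them.
        """
        spacing = float(spacing)
        if np.allclose(self.spacing, spacing):
            return self
        from scipy.ndimage import map_coordinates
        extent = np.array(self.shape) * self.spacing
        shape = np.maximum(np.round(extent / spacing).astype(int), 1)
        lo = self.lower_corner()
        ax = [lo[a] + spacing / 2.0 + np.arange(shape[a]) * spacing
              for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        idx = [(g - self.origin[a]) / self.spacing[a]
               for a, g in enumerate((gx, gy, gz))]
        mat = map_coordinates(self.material_index.astype(np.int16), idx,
                              order=0, mode="nearest").astype(np.int16)
        return VoxelPhantom(np.ascontiguousarray(mat),
                            np.array([spacing] * 3), lo + spacing / 2.0,
                            self.materials)

    # ---- persistence ------------------------------------------------------

    def save(self, path) -> None:
        mats = json.dumps([asdict(m) for m in self.materials])
        arrays = dict(material_index=self.material_index.astype(np.int16),
                      spacing=self.spacing, origin=self.origin,
                      materials_json=np.frombuffer(mats.encode(), dtype=np.uint8))
        if self.hu is not None:
            arrays["hu"] = self.hu
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "VoxelPhantom":
        with np.load(path) as z:
            mats = json.loads(bytes(z["materials_json"]).decode())
            lib = MaterialLibrary([MaterialSpec(**m) for m in mats])
            hu = z["hu"] if "hu" in z.files else None
            return cls(material_index=z["material_index"].astype(np.int16),
                       spacing=z["spacing"], origin=z["origin"],
                       materials=lib, hu=hu)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_slab_phantom(layers, lateral_size, spacing,
                       materials: MaterialLibrary | None = None,
                       surrounding: str = "air") -> VoxelPhantom:
    """Stack of laterally infinite (within the grid) material layers along z.

    Parameters
    ----------
    layers : sequence of (material_name, thickness_mm)
        Ordered upstream to downstream along +z.  Partial-voxel layers are
        assigned by dominant occupancy within each voxel slab.
    lateral_size : float or (float, float)
        Lateral x/y extent in mm.
    spacing : float or (float, float, float)
        Isotropic or per-axis voxel size in mm.
    """
    materials = materials if materials is not None else MaterialLibrary()
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=float)), (3,)).copy()
    lat = np.broadcast_to(np.atleast_1d(np.asarray(lateral_size, dtype=float)), (2,)).copy()

    thicknesses = np.array([float(t) for _, t in layers])
    if np.any(thicknesses < 0):
        raise ValueError("layer thicknesses must be >= 0")
    for name, _ in layers:
        if name not in materials:
            raise KeyError(f"unknown material {name!r}")

    z_total = thicknesses.sum()
    nz = max(int(round(z_total / spacing[2])), 1)
    nx = max(int(round(lat[0] / spacing[0])), 1)
    ny = max(int(round(lat[1] / spacing[1])), 1)

    bounds = np.concatenate([[0.0], np.cumsum(thicknesses)])
    # a layer thinner than half a voxel can be swallowed by dominant-occupancy
    for name, t in layers:
        if 0 < t < spacing[2] / 2.0:
            warnings.warn(f"layer {name!r} of {t} mm is thinner than half a "
                          f"voxel ({spacing[2]} mm) and may not be represented",
                          stacklevel=2)

    grid = np.empty((nx, ny, nz), dtype=np.int16)
    z_edges = np.arange(nz + 1) * spacing[2]
    for k in range(nz):
        z0, z1 = z_edges[k], z_edges[k + 1]
        # overlap of [z0, z1) with each layer; dominant material wins
        lo = np.maximum(bounds[:-1], z0)
        hi = np.minimum(bounds[1:], z1)
        overlap = np.clip(hi - lo, 0.0, None)
        if overlap.sum() <= 0:
            idx = materials.index(surrounding)
        else:
            idx = materials.index(layers[int(np.argmax(overlap))][0])
        grid[:, :, k] = idx

    origin = np.array([-lat[0] / 2.0 + spacing[0] / 2.0,
                       -lat[1] / 2.0 + spacing[1] / 2.0,
                       spacing[2] / 2.0])
    return VoxelPhantom(grid, spacing, origin, materials)


@dataclass
class NeckAnalogConfig:
    """Geometry of the synthetic neck analog (all lengths in mm).

    An elliptical soft-tissue cylinder (axis along x, wider than tall like a
    real neck section) holds a bone annulus with an air channel at its
    center, offset from the cylinder axis.  The cylinder is cut flat just
    past the bone and rests on a downstream solid-water region where
    measurement planes are placed.  The air/bone sizes are chosen so a
    single anterior beam sees strong discrete lateral heterogeneity, the
    regime in which slab-approximation dose engines break down, while the
    smooth outer contour keeps entrance obliquity anatomically moderate.
    """

    tissue_radius: float = 70.0              # horizontal (y) semi-axis
    tissue_radius_vertical: float = 32.0     # beam-direction (z) semi-axis
    bone_inner_radius: float = 6.0
    bone_outer_radius: float = 10.0
    air_radius: float = 4.5
    #: (y, z) offset of the bone/air complex from the cylinder axis
    complex_offset: tuple[float, float] = (0.0, -8.0)
    #: flat-cut plane, mm downstream of the cylinder axis
    cut_offset: float = 8.0
    solid_water_thickness: float = 45.0
    upstream_air: float = 5.0
    lateral_size: tuple[float, float] = (100.0, 150.0)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if not (self.air_radius <= self.bone_inner_radius
                <= self.bone_outer_radius
                <= min(self.tissue_radius, self.tissue_radius_vertical)):
            raise ValueError("radii must be nested: air <= bone inner <= "
                             "bone outer <= tissue semi-axes")


def build_neck_analog(config: NeckAnalogConfig | None = None,
                      materials: MaterialLibrary | None = None) -> VoxelPhantom:
    cfg = config if config is not None else NeckAnalogConfig()
    materials = materials if materials is not None else MaterialLibrary()

    sp = float(cfg.spacing)
    spacing = np.array([sp, sp, sp])
    lat = np.asarray(cfg.lateral_size, dtype=float)
    rz = cfg.tissue_radius_vertical
    cyl_y, cyl_z = 0.0, cfg.upstream_air + rz
    z_cut = cyl_z + cfg.cut_offset
    if z_cut <= cyl_z - rz:
        raise ValueError("cut plane removes the entire cylinder")
    z_total = z_cut + cfg.solid_water_thickness
    nx = int(round(lat[0] / sp))
    ny = int(round(lat[1] / sp))
    nz = int(round(z_total / sp))
    origin = np.array([-lat[0] / 2 + sp / 2, -lat[1] / 2 + sp / 2, sp / 2])

    y = origin[1] + np.arange(ny) * sp
    z = origin[2] + np.arange(nz) * sp
    yy, zz = np.meshgrid(y, z, indexing="ij")

    r2_cyl = ((yy - cyl_y) / cfg.tissue_radius) ** 2 \
        + ((zz - cyl_z) / rz) ** 2
    cy, cz = cyl_y + cfg.complex_offset[0], cyl_z + cfg.complex_offset[1]
    r2_cpx = (yy - cy) ** 2 + (zz - cz) ** 2

    section = np.full((ny, nz), materials.index("air"), dtype=np.int16)
    in_cyl = (r2_cyl <= 1.0) & (zz < z_cut)
    section[in_cyl] = materials.index("soft_tissue")
    in_bone = in_cyl & (r2_cpx <= cfg.bone_outer_radius ** 2) \
                     & (r2_cpx > cfg.bone_inner_radius ** 2)
    section[in_bone] = materials.index("bone")
    if cfg.air_radius > 0:
        in_air = in_cyl & (r2_cpx <= cfg.air_radius ** 2)
        section[in_air] = materials.index("air")
    section[:, zz[0] >= z_cut] = materials.index("solid_water")

    grid = np.broadcast_to(section[None, :, :], (nx, ny, nz)).astype(np.int16).copy()
    return VoxelPhantom(grid, spacing, origin, materials)


def neck_cut_plane_z(cfg: NeckAnalogConfig) -> float:
    """z position (mm) of the flat cut / solid-water surface."""
    return cfg.upstream_air + cfg.tissue_radius_vertical + cfg.cut_offset


@dataclass
class BreastAnalogConfig:
    """Water hemisphere (the prosthesis analog) resting on solid-water slabs."""

    dome_radius: float = 45.0
    slab_thickness: float = 40.0
    upstream_air: float = 5.0
    lateral_size: tuple[float, float] = (110.0, 110.0)
    spacing: float = 1.0


def build_breast_analog(config: BreastAnalogConfig | None = None,
                        materials: MaterialLibrary | None = None) -> VoxelPhantom:
    cfg = config if config is not None else BreastAnalogConfig()
    materials = materials if materials is not None else MaterialLibrary()
    sp = float(cfg.spacing)
    lat = np.asarray(cfg.lateral_size, dtype=float)
    z_dome0 = cfg.upstream_air
    z_slab0 = z_dome0 + cfg.dome_radius
    z_total = z_slab0 + cfg.slab_thickness
    nx = int(round(lat[0] / sp)); ny = int(round(lat[1] / sp))
    nz = int(round(z_total / sp))
    origin = np.array([-lat[0] / 2 + sp / 2, -lat[1] / 2 + sp / 2, sp / 2])

    x = origin[0] + np.arange(nx) * sp
    y = origin[1] + np.arange(ny) * sp
    z = origin[2] + np.arange(nz) * sp
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    grid = np.full((nx, ny, nz), materials.index("air"), dtype=np.int16)
    # hemisphere with flat face down on the slab, dome pointing upstream (-z)
    dome = (xx ** 2 + yy ** 2 + (zz - z_slab0) ** 2 <= cfg.dome_radius ** 2) \
           & (zz < z_slab0)
    grid[dome] = materials.index("water")
    grid[:, :, z >= z_slab0] = materials.index("solid_water")
    return VoxelPhantom(grid, np.array([sp, sp, sp]), origin, materials)


# ---------------------------------------------------------------------------
# water-equivalent depth raytracing
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trace_wed_kernel(rsp, sp, lo, hi, p0, u, depths, out):
    """Exact voxel raytrace: cumulative WED at the sorted geometric ``depths``.

    Material outside the grid contributes zero.  Returns 1 if the ray
    intersects the grid, else 0.
    """
    nq = depths.shape[0]
    for i in range(nq):
        out[i] = 0.0
    # slab-clip ray against the grid bounding box
    tmin = 0.0
    tmax = depths[nq - 1] if nq > 0 else 0.0
    for a in range(3):
        if abs(u[a]) < 1e-12:
            if p0[a] < lo[a] or p0[a] >= hi[a]:
                return 0
        else:
            t1 = (lo[a] - p0[a]) / u[a]
            t2 = (hi[a] - p0[a]) / u[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmin >= tmax:
        return 0

    nx, ny, nz = rsp.shape
    # entry voxel
    t = tmin
    eps = 1e-9
    px = p0[0] + (t + eps) * u[0]
    py = p0[1] + (t + eps) * u[1]
    pz = p0[2] + (t + eps) * u[2]
    ix = int(np.floor((px - lo[0]) / sp[0]))
    iy = int(np.floor((py - lo[1]) / sp[1]))
    iz = int(np.floor((pz - lo[2]) / sp[2]))
    if ix < 0: ix = 0
    if iy < 0: iy = 0
    if iz < 0: iz = 0
    if ix > nx - 1: ix = nx - 1
    if iy > ny - 1: iy = ny - 1
    if iz > nz - 1: iz = nz - 1

    stepx = 1 if u[0] > 0 else -1
    stepy = 1 if u[1] > 0 else -1
    stepz = 1 if u[2] > 0 else -1
    big = 1e30
    if abs(u[0]) > 1e-12:
        nextb = lo[0] + (ix + (1 if stepx > 0 else 0)) * sp[0]
        tx = (nextb - p0[0]) / u[0]
        dtx = sp[0] / abs(u[0])
    else:
        tx = big; dtx = big
    if abs(u[1]) > 1e-12:
        nextb = lo[1] + (iy + (1 if stepy > 0 else 0)) * sp[1]
        ty = (nextb - p0[1]) / u[1]
        dty = sp[1] / abs(u[1])
    else:
        ty = big; dty = big
    if abs(u[2]) > 1e-12:
        nextb = lo[2] + (iz + (1 if stepz > 0 else 0)) * sp[2]
        tz = (nextb - p0[2]) / u[2]
        dtz = sp[2] / abs(u[2])
    else:
        tz = big; dtz = big

    wed = 0.0
    qi = 0
    # queries entirely before entry get zero
    while qi < nq and depths[qi] <= tmin:
        out[qi] = 0.0
        qi += 1

    while t < tmax:
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn > tmax:
            tn = tmax
        r = rsp[ix, iy, iz]
        while qi < nq and depths[qi] <= tn:
            out[qi] = wed + (depths[qi] - t) * r
            qi += 1
        wed += (tn - t) * r
        t = tn
        if t >= tmax:
            break
        if tx <= ty and tx <= tz:
            ix += stepx; tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif ty <= tz:
            iy += stepy; ty += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stepz; tz += dtz
            if iz < 0 or iz >= nz:
                break
    while qi < nq:
        out[qi] = wed
        qi += 1
    return 1


def wed_at_depths(phantom: VoxelPhantom, entry, direction, depths) -> np.ndarray:
    """Cumulative water-equivalent depth at each sorted geometric depth."""
    depths = np.ascontiguousarray(depths, dtype=np.float64)
    out = np.empty_like(depths)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    hit = _trace_wed_kernel(np.ascontiguousarray(phantom.rsp_grid),
                            phantom.spacing, phantom.lower_corner(),
                            phantom.upper_corner(),
                            np.asarray(entry, dtype=float), u, depths, out)
    if not hit:
        warnings.warn("ray does not intersect the phantom; WED = 0", stacklevel=2)
    return out


def wed_along_ray(phantom: VoxelPhantom, entry, direction,
                  geometric_depth: float) -> float:
    """Water-equivalent depth of a point ``geometric_depth`` mm along the ray.

    Sum of (segment length x RSP) over traversed voxels via exact raytracing.
    A ray that misses the phantom returns 0 with a warning.
    """
    if geometric_depth < 0:
        raise ValueError("geometric_depth must be >= 0")
    return float(wed_at_depths(phantom, entry, direction,
                               np.array([float(geometric_depth)]))[0])
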