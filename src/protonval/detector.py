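"""Virtual planar ionization-chamber array (MatriXX PT style) and OPG I/O.

The detector is a square lattice of point-sampling channels at 7 mm pitch
with 6 mm of water-equivalent buildup in front of the measurement plane, so
a detector placed directly on the phantom surface measures at a
water-equivalent depth of 6 mm; additional solid-water slabs between the
phantom and the detector push the plane deeper by their WET.  Channels apply
a multiplicative cross-calibration factor and independent Gaussian noise.

Planes are persisted as a small, self-describing ASCII dialect modeled on
the "Omni Pro Generic" exports of commercial array software: a tagged header
followed by a row-major value matrix (exact grammar in ``write_opg``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dose import DoseCube
from .materials import SOLID_WATER_RSP

DEFAULT_PITCH_MM = 7.0
DEFAULT_BUILDUP_WET_MM = 6.0


@dataclass
class MeasuredPlane:
    values: np.ndarray               # Gy, shape (nx, ny)
    pitch: float                     # mm
    origin: np.ndarray               # (x0, y0) mm of channel [0, 0]
    d_m: float                       # water-equivalent depth below the surface
    buildup_wet: float = DEFAULT_BUILDUP_WET_MM
    calibration_factor: float = 1.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if np.any(self.values < 0):
            raise ValueError("measured values must be nonnegative")
        if self.d_m < self.buildup_wet - 1e-9:
            raise ValueError("d_m cannot be shallower than the buildup WET")

    def channel_positions(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + np.arange(self.values.shape[0]) * self.pitch
        y = self.origin[1] + np.arange(self.values.shape[1]) * self.pitch
        return x, y


def measurement_geometry(stack_mm: float, medium_rsp: float = SOLID_WATER_RSP,
                         buildup_wet: float = DEFAULT_BUILDUP_WET_MM
                         ) -> tuple[float, float]:
    """(d_m, geometric depth below the surface) for a solid-water stack.

    d_m = stack WET + buildup WET; the geometric depth converts the total
    WET back through the stack medium's stopping-power ratio.
    """
    d_m = stack_mm * medium_rsp + buildup_wet
    geometric = d_m / medium_rsp
    return d_m, geometric


def simulate_measurement(cube: DoseCube, stack_mm: float, surface_z: float,
                         noise_sigma: float = 0.01,
                         calibration_factor: float = 1.0,
                         seed: int = 0,
                         pitch: float = DEFAULT_PITCH_MM,
                         n_detectors: tuple[int, int] | None = None,
                         center=(0.0, 0.0),
                         medium_rsp: float = SOLID_WATER_RSP,
                         buildup_wet: float = DEFAULT_BUILDUP_WET_MM,
                         averaging_diameter_mm: float = 0.0) -> MeasuredPlane:
    """Sample a dose cube the way the detector stack would measure it.

    The detector sits below ``stack_mm`` of solid water whose surface is at
    ``surface_z`` (mm, cube frame).  The effective plane lies at
    d_m = stack x 1.03 + 6 mm WET below that surface; values are trilinear
    samples of the cube at the channel lattice, times the calibration
    factor, times independent (1 + Gaussian) channel noise.  An optional
    averaging kernel emulates the finite chamber diameter (off by default:
    channels are point samples).
    """
    d_m, geometric = measurement_geometry(stack_mm, medium_rsp, buildup_wet)
    z = surface_z + geometric
    z_min = cube.origin[2] - cube.spacing[2] / 2.0
    z_max = z_min + cube.shape[2] * cube.spacing[2]
    if not (z_min <= z <= z_max):
        raise ValueError(
            f"measurement plane z={z:.2f} mm outside the cube "
            f"[{z_min:.2f}, {z_max:.2f}]; valid stack range is "
            f"[{(z_min - surface_z) * medium_rsp - buildup_wet:.1f}, "
            f"{(z_max - surface_z) * medium_rsp - buildup_wet:.1f}] mm WET")

    if n_detectors is None:
        ext_x = cube.shape[0] * cube.spacing[0]
        ext_y = cube.shape[1] * cube.spacing[1]
        n_detectors = (max(int((ext_x - 2 * pitch) / pitch), 1),
                       max(int((ext_y - 2 * pitch) / pitch), 1))
    nx, ny = n_detectors
    x0 = center[0] - (nx - 1) / 2.0 * pitch
    y0 = center[1] - (ny - 1) / 2.0 * pitch
    x = x0 + np.arange(nx) * pitch
    y = y0 + np.arange(ny) * pitch

    if averaging_diameter_mm > 0:
        # average over a small disc of sample points (chamber response)
        r = averaging_diameter_mm / 2.0
        offs = [(0.0, 0.0)] + [(r * np.cos(a), r * np.sin(a))
                               for a in np.linspace(0, 2 * np.pi, 6,
                                                    endpoint=False)]
        acc = np.zeros((nx, ny))
        for ox, oy in offs:
            xx, yy = np.meshgrid(x + ox, y + oy, indexing="ij")
            pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
            acc += cube.interp_points(pts).reshape(nx, ny)
        vals = acc / len(offs)
    else:
        xx, yy = np.meshgrid(x, y, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
        vals = cube.interp_points(pts).reshape(nx, ny)

    vals = vals * calibration_factor
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + noise_sigma * rng.standard_normal(vals.shape))
    vals = np.clip(vals, 0.0, None)
    return MeasuredPlane(values=vals, pitch=pitch, origin=np.array([x0, y0]),
                         d_m=d_m, buildup_wet=buildup_wet,
                         calibration_factor=calibration_factor,
                         noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# OPG-style ASCII
# ---------------------------------------------------------------------------

_OPG_OPEN = "<opimrtascii>"
_OPG_CLOSE = "</opimrtascii>"


def write_opg(plane: MeasuredPlane, path) -> None:
    """Write a measured plane as OPG-style ASCII.

    Grammar: ``<opimrtascii>`` / ``<asciiheader>`` block of ``Key: value``
    lines / ``</asciiheader>`` / ``<asciibody>`` with one row of
    whitespace-separated Gy values per detector row (row-major, x index
    fastest along a line) / ``</asciibody>`` / ``</opimrtascii>``.
    """
    nx, ny = plane.values.shape
    lines = [
        _OPG_OPEN,
        "<asciiheader>",
        "Data Type: Absolute Dose",
        "Data Unit: Gy",
        "Length Unit: mm",
        f"Plane Depth [mm]: {plane.d_m:.6f}",
        f"Buildup WET [mm]: {plane.buildup_wet:.6f}",
        f"Calibration Factor: {plane.calibration_factor:.8f}",
        f"Noise Sigma: {plane.noise_sigma:.8f}",
        f"Detector Pitch [mm]: {plane.pitch:.6f}",
        f"Origin [mm]: {plane.origin[0]:.6f} {plane.origin[1]:.6f}",
        f"Rows: {ny}",
        f"Cols: {nx}",
        "</asciiheader>",
        "<asciibody>",
    ]
    for j in range(ny):
        lines.append(" ".join(f"{plane.values[i, j]:.8e}" for i in range(nx)))
    lines += ["</asciibody>", _OPG_CLOSE, ""]
    Path(path).write_text("\n".join(lines))


def read_opg(path) -> MeasuredPlane:
    """Parse an OPG-style ASCII plane; errors name the offending line."""
    raw = Path(path).read_text()
    lines = raw.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    header: dict[str, str] = {}
    body: list[list[float]] = []
    mode = None
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        low = s.lower()
        if low == _OPG_OPEN or low == _OPG_CLOSE:
            continue
        if low == "<asciiheader>":
            mode = "header"
            continue
        if low == "</asciiheader>":
            mode = None
            continue
        if low == "<asciibody>":
            mode = "body"
            continue
        if low == "</asciibody>":
            mode = None
            continue
        if mode == "header":
            if ":" not in s:
                raise ValueError(f"{path}: line {ln}: malformed header line {s!r}")
            key, _, val = s.partition(":")
            header[key.strip().lower()] = val.strip()
        elif mode == "body":
            try:
                body.append([float(tok) for tok in s.split()])
            except ValueError:
                raise ValueError(f"{path}: line {ln}: non-numeric value in body") \
                    from None
        else:
            raise ValueError(f"{path}: line {ln}: content outside tagged blocks")

    def need(key):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
        return header[key]

    ny = int(need("rows"))
    nx = int(need("cols"))
    if len(body) != ny:
        raise ValueError(f"{path}: header declares {ny} rows but the body has "
                         f"{len(body)}")
    for j, row in enumerate(body):
        if len(row) != nx:
            raise ValueError(f"{path}: body row {j + 1} has {len(row)} values, "
                             f"expected {nx}")
    vals = np.array(body).T           # rows are y, columns x
    origin = np.array([float(tok) for tok in need("origin [mm]").split()])
    return MeasuredPlane(values=vals,
                         pitch=float(need("detector pitch [mm]")),
                         origin=origin,
                         d_m=float(need("plane depth [mm]")),
                         buildup_wet=float(header.get("buildup wet [mm]",
                                                      DEFAULT_BUILDUP_WET_MM)),
                         calibration_factor=float(header.get(
                             "calibration factor", 1.0)),
                         noise_sigma=float(header.get("noise sigma", 0.0)))
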