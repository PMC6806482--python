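"""Material definitions and the HU calibration used by the synthetic phantoms.

A material is summarized by five numbers: mass density, relative stopping
power versus water (RSP), radiation length, mean ionization energy, and a
multiplier on water's macroscopic nonelastic nuclear cross section.  Elemental
composition is deliberately not resolved; RSP plus the nuclear multiplier
stand in for it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    mass_density: float          # g/cm^3
    rsp: float                   # relative stopping power vs water
    radiation_length: float      # g/cm^2
    mean_ionization_energy: float  # eV
    nuclear_scale: float         # multiplier on water's nonelastic cross section

    def __post_init__(self) -> None:
        if self.name.lower() != "air" and self.mass_density <= 0:
            raise ValueError(f"{self.name}: mass_density must be > 0")
        if self.rsp < 0:
            raise ValueError(f"{self.name}: rsp must be >= 0")

    @property
    def x0_mm(self) -> float:
        """Radiation length in mm at this material's density."""
        return self.radiation_length / self.mass_density * 10.0


#: Water-equivalent thickness ratio of the solid-water slab material.
SOLID_WATER_RSP = 1.03

_DEFAULTS = [
    MaterialSpec("air", 0.0012, 0.001, 36.62, 85.7, 0.0012),
    MaterialSpec("water", 1.000, 1.000, 36.08, 75.0, 1.000),
    MaterialSpec("solid_water", 1.045, SOLID_WATER_RSP, 36.08, 75.0, 1.03),
    MaterialSpec("soft_tissue", 1.040, 1.040, 36.08, 75.0, 1.04),
    # typical cortical-bone surrogate values
    MaterialSpec("bone", 1.85, 1.60, 16.64, 112.0, 1.65),
    MaterialSpec("detector_buildup", 1.00, 1.00, 36.08, 75.0, 1.00),
]


class MaterialLibrary:
    """Ordered, name-keyed registry of :class:`MaterialSpec`.

    The registry order defines the integer material indices stored in voxel
    phantoms, so it must stay stable for a given phantom.
    """

    def __init__(self, materials=None):
        self._materials: list[MaterialSpec] = []
        self._index: dict[str, int] = {}
        for m in (materials if materials is not None else _DEFAULTS):
            self.add(m)

    def add(self, material: MaterialSpec) -> int:
        if material.name in self._index:
            raise ValueError(f"material {material.name!r} already registered")
        self._index[material.name] = len(self._materials)
        self._materials.append(material)
        return self._index[material.name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self._materials)

    def __iter__(self):
        return iter(self._materials)

    def __getitem__(self, key):
        if isinstance(key, str):
            try:
                return self._materials[self._index[key]]
            except KeyError:
                raise KeyError(f"unknown material {key!r}; registered: "
                               f"{sorted(self._index)}") from None
        return self._materials[key]

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"unknown material {name!r}; registered: "
                           f"{sorted(self._index)}")
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._materials]

    def rsp_table(self) -> np.ndarray:
        return np.array([m.rsp for m in self._materials])

    def density_table(self) -> np.ndarray:
        return np.array([m.mass_density for m in self._materials])

    def x0_table(self) -> np.ndarray:
        return np.array([m.x0_mm for m in self._materials])

    def nuclear_table(self) -> np.ndarray:
        return np.array([m.nuclear_scale for m in self._materials])

    # ---- YAML persistence -------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {m.name: {k: v for k, v in asdict(m).items() if k != "name"}
                   for m in self._materials}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "MaterialLibrary":
        payload = yaml.safe_load(Path(path).read_text())
        mats = [MaterialSpec(name=name, **fields) for name, fields in payload.items()]
        return cls(mats)


#: HU calibration anchors: 3-point piecewise-linear (air / water / bone).
HU_ANCHORS = np.array([-1000.0, 0.0, 1500.0])
HU_DENSITY = np.array([0.0012, 1.000, 1.85])
HU_RSP = np.array([0.001, 1.000, 1.60])
HU_RANGE = (-1024.0, 3000.0)


def hu_to_density_rsp(hu):
    """Piecewise-linear HU -> (mass density, RSP) calibration.

    Values outside [-1024, 3000] are clamped with a warning.  The mapping is
    monotone nondecreasing in both outputs by construction of the anchors.
    """
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < HU_RANGE[0]) or np.any(hu > HU_RANGE[1]):
        warnings.warn("HU outside calibration range; clamping", stacklevel=2)
        hu = np.clip(hu, *HU_RANGE)
    density = np.interp(hu, HU_ANCHORS, HU_DENSITY)
    rsp = np.interp(hu, HU_ANCHORS, HU_RSP)
    return density, rsp


def hu_to_material(hu: float) -> MaterialSpec:
    """Map a Hounsfield value to an ad-hoc MaterialSpec via the 3-anchor curve.

    Radiation length and nuclear scale are interpolated between the air,
    water and bone defaults on the same anchors.
    """
    density, rsp = hu_to_density_rsp(float(hu))
    density = float(density)
    rsp = float(rsp)
    hu_c = float(np.clip(hu, *HU_RANGE))
    x0 = float(np.interp(hu_c, HU_ANCHORS, [36.62, 36.08, 16.64]))
    ion = float(np.interp(hu_c, HU_ANCHORS, [85.7, 75.0, 112.0]))
    nuc = float(np.interp(hu_c, HU_ANCHORS, [0.0012, 1.0, 1.65]))
    return MaterialSpec(f"hu_{hu:+.0f}", max(density, 1e-4), rsp, x0, ion, nuc)
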