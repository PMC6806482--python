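"""PBS beamline and plan data model: energy layers, Gaussian spots, range
shifter, air gap, and JSON round-tripping of plans.

The range shifter is modeled purely as upstream water-equivalent thickness
(WET): the analytical engine offsets the depth at which the IDD is evaluated,
and the Monte Carlo engine pulls the initial energy back by the same WET and
adds the corresponding Bohr energy spread.  Spot size in air at the phantom
surface is a configurable linear function of energy plus a growth term across
the air gap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import physics


@dataclass
class BeamLineConfig:
    range_shifter_wet: float = 75.0        # mm water-equivalent
    air_gap: float = 20.0                  # mm between range shifter and phantom
    #: sigma(E) = sigma_a - sigma_b * (E - sigma_e0), mm at the nozzle exit
    sigma_a: float = 12.0
    sigma_b: float = 0.035
    sigma_e0: float = 70.0
    #: extra in-air sigma growth per mm of air gap (range-shifter scatter)
    sigma_growth_per_mm_airgap: float = 0.05
    available_energies: tuple = tuple(float(e) for e in range(70, 231))
    #: number of protons delivered per monitor unit (sets the absolute scale)
    protons_per_mu: float = 1.0e9

    def __post_init__(self) -> None:
        if self.range_shifter_wet < 0 or self.air_gap < 0:
            raise ValueError("range_shifter_wet and air_gap must be >= 0")
        e = np.asarray(self.available_energies, dtype=float)
        if e.size == 0 or np.any(np.diff(e) <= 0):
            raise ValueError("available_energies must be strictly increasing")

    def spot_sigma_air(self, energy_mev: float) -> float:
        """In-air spot sigma (mm) at the phantom surface."""
        s = self.sigma_a - self.sigma_b * (float(energy_mev) - self.sigma_e0)
        s += self.sigma_growth_per_mm_airgap * self.air_gap
        return max(s, 2.0)

    @property
    def mu_to_gy_calibration(self) -> float:
        """Gy mm^2 per MU per unit water stopping power (MeV/mm)."""
        return self.protons_per_mu * physics.GY_MM2_PER_MEV_PER_MM

    def nearest_energy(self, energy_mev: float) -> float:
        e = np.asarray(self.available_energies, dtype=float)
        return float(e[np.argmin(np.abs(e - energy_mev))])

    def energy_at_phantom(self, nominal_energy: float) -> float:
        """Kinetic energy after traversing the range shifter WET."""
        r = physics.range_from_energy(nominal_energy) - self.range_shifter_wet
        if r <= 0:
            raise ValueError(f"range shifter ({self.range_shifter_wet} mm WET) "
                             f"stops a {nominal_energy} MeV beam")
        return float(physics.energy_from_range(r))


@dataclass
class Spot:
    x: float           # mm at the isocenter plane, beam frame
    y: float
    energy: float      # MeV (nominal machine energy)
    weight: float      # MU

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class EnergyLayer:
    energy: float
    spots: list

    @property
    def total_mu(self) -> float:
        return float(sum(s.weight for s in self.spots))


@dataclass
class Beam:
    direction: np.ndarray                 # unit vector, beam travel direction
    beamline: BeamLineConfig
    layers: list
    name: str = "beam"

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            self.direction = self.direction / n
        for layer in self.layers:
            if len(layer.spots) == 0:
                raise ValueError("every energy layer must be nonempty")
            for s in layer.spots:
                if s.energy not in self.beamline.available_energies:
                    raise ValueError(f"spot energy {s.energy} not available")

    def all_spots(self) -> list:
        return [s for layer in self.layers for s in layer.spots]

    @property
    def total_mu(self) -> float:
        return float(sum(l.total_mu for l in self.layers))


@dataclass
class PBSPlan:
    beams: list
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.beams) == 0:
            raise ValueError("a plan needs at least one beam")

    @property
    def n_spots(self) -> int:
        return sum(len(l.spots) for b in self.beams for l in b.layers)

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))

    def scaled(self, factor: float) -> "PBSPlan":
        """New plan with every spot weight multiplied by ``factor``."""
        beams = []
        for b in self.beams:
            layers = [EnergyLayer(l.energy,
                                  [Spot(s.x, s.y, s.energy, s.weight * factor)
                                   for s in l.spots]) for l in b.layers]
            beams.append(Beam(b.direction.copy(), b.beamline, layers, b.name))
        return PBSPlan(beams, self.label)

    # ---- JSON persistence -------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "label": self.label,
            "beams": [{
                "name": b.name,
                "direction": list(b.direction),
                "beamline": asdict(b.beamline) | {
                    "available_energies": list(b.beamline.available_energies)},
                "layers": [{
                    "energy": l.energy,
                    "spots": [[s.x, s.y, s.weight] for s in l.spots],
                } for l in b.layers],
            } for b in self.beams],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PBSPlan":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        beams = []
        for b in payload["beams"]:
            blc = dict(b["beamline"])
            blc["available_energies"] = tuple(blc["available_energies"])
            beamline = BeamLineConfig(**blc)
            layers = [EnergyLayer(l["energy"],
                                  [Spot(x, y, l["energy"], w)
                                   for x, y, w in l["spots"]])
                      for l in b["layers"]]
            beams.append(Beam(np.array(b["direction"]), beamline, layers,
                              b.get("name", "beam")))
        return cls(beams, payload.get("label", ""))


def beam_frame(direction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2, d) with d the beam direction.

    For a +z beam this reduces to the lab axes (e1 = x, e2 = y), so spot
    (x, y) coordinates coincide with lab coordinates in the en-face case.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d
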