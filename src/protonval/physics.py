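"""Proton transport physics primitives shared by both dose engines.

All closed forms here are deliberately simple, parameterized models of the
standard therapeutic-proton physics:

* range-energy: Bragg-Kleeman power law ``R = alpha * E**p`` (R in mm of
  water, E in MeV),
* stopping power: the derivative of the power law,
* multiple Coulomb scattering: Gaussian small-angle theory with a Highland
  width,
* energy-loss straggling: Bohr's Gaussian approximation with variance
  proportional to path length.

Both the analytical pencil-beam engine and the Monte Carlo engine consume
exactly these functions, so cross-engine comparisons probe the transport
approximations (slab geometry vs. voxel-by-voxel stepping), not differences
in the underlying range-energy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROTON_MASS_MEV = 938.272

#: Bragg-Kleeman coefficient, mm water per MeV**p (0.0022 cm MeV^-p).
ALPHA_MM = 0.022
#: Bragg-Kleeman exponent.
P_EXP = 1.77

#: Bohr energy-straggling variance coefficient for water, MeV^2 per mm of
#: water-equivalent path (0.157 * Z/A * rho * t with Z/A = 0.555).
BOHR_VAR_MM = 0.0087

#: Radiation length of water in mm (36.08 g/cm^2 at unit density).
WATER_X0_MM = 360.8

#: Highland's logarithmic correction is frozen at this reference thickness so
#: the per-step scattering variance is exactly additive over sub-steps.
HIGHLAND_REF_THICKNESS_MM = 10.0


def range_from_energy(energy_mev, alpha_mm: float = ALPHA_MM, p: float = P_EXP):
    """CSDA range in mm of water for protons of kinetic energy ``energy_mev``."""
    return alpha_mm * np.asarray(energy_mev, dtype=float) ** p


def energy_from_range(range_mm, alpha_mm: float = ALPHA_MM, p: float = P_EXP):
    """Inverse of :func:`range_from_energy` (MeV for a residual range in mm)."""
    return (np.asarray(range_mm, dtype=float) / alpha_mm) ** (1.0 / p)


def stopping_power_water(energy_mev, alpha_mm: float = ALPHA_MM, p: float = P_EXP):
    """Mass-collision stopping power of water in MeV/mm.

    Differentiating ``R = alpha E^p`` gives ``dE/dz = E^(1-p) / (alpha p)``,
    the parameterized stand-in for the Bethe-Bloch formula used throughout.
    """
    e = np.asarray(energy_mev, dtype=float)
    return e ** (1.0 - p) / (alpha_mm * p)


def momentum_velocity(energy_mev):
    """Relativistic ``p*v`` in MeV for a proton of kinetic energy E."""
    e = np.asarray(energy_mev, dtype=float)
    return e * (e + 2.0 * PROTON_MASS_MEV) / (e + PROTON_MASS_MEV)


def highland_log_correction(x0_mm: float = WATER_X0_MM,
                            t_ref_mm: float = HIGHLAND_REF_THICKNESS_MM) -> float:
    """Highland's ``1 + 1/9 log10(t/X0)`` factor at the frozen reference thickness."""
    return 1.0 + np.log10(t_ref_mm / x0_mm) / 9.0


def highland_sigma(energy_mev, step_mm, x0_mm: float = WATER_X0_MM):
    """Gaussian width (radians) of the projected scattering angle for one step.

    The log correction is evaluated at a fixed reference thickness rather than
    at the actual step, which makes the angular variance strictly additive
    when a step is subdivided (the Gaussian small-angle limit of
    Goudsmit-Saunderson theory demands additivity).
    """
    c = highland_log_correction(x0_mm)
    t = np.asarray(step_mm, dtype=float)
    return (14.1 / momentum_velocity(energy_mev)) * np.sqrt(t / x0_mm) * c


def scattering_power(energy_mev, x0_mm: float = WATER_X0_MM):
    """T(E) = d<theta_x^2>/dz in rad^2/mm, consistent with :func:`highland_sigma`."""
    c = highland_log_correction(x0_mm)
    return (14.1 * c / momentum_velocity(energy_mev)) ** 2 / x0_mm


def range_straggling_sigma(energy_mev, alpha_mm: float = ALPHA_MM,
                           p: float = P_EXP, bohr_var_mm: float = BOHR_VAR_MM):
    """RMS spread of the stopping depth (mm) from Bohr energy straggling.

    Propagating the Gaussian energy-loss variance to a depth variance gives
    ``sigma_R^2 = integral_0^E0 k_B / S(E)^3 dE`` which evaluates in closed
    form for the power-law stopping power.
    """
    e = np.asarray(energy_mev, dtype=float)
    n = 3.0 * p - 2.0
    var = bohr_var_mm * (alpha_mm * p) ** 3 * e ** n / n
    return np.sqrt(var)


@dataclass
class NuclearModel:
    """Parameterized nonelastic nuclear-interaction data for protons in water.

    The macroscopic nonelastic cross section is piecewise linear in energy,
    zero below ``threshold_mev``, and anchored at magnitudes typical of water
    (about 1.2 %% per cm above 100 MeV).  On interaction the incident kinetic
    energy is split into fixed fractions: a secondary proton that continues in
    Class II transport, deuteron and alpha fragments deposited along
    straight-line CSDA tracks, neutral products (neutrons, gammas) whose
    energy leaves the simulation, and heavy recoils absorbed locally.
    """

    threshold_mev: float = 8.0
    energy_grid_mev: np.ndarray = field(
        default_factory=lambda: np.array([8.0, 20.0, 50.0, 100.0, 150.0, 250.0]))
    #: macroscopic nonelastic cross section in water, mm^-1
    sigma_mm: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 4.0e-4, 9.0e-4, 1.1e-3, 1.2e-3, 1.2e-3]))
    frac_proton: float = 0.55
    frac_deuteron: float = 0.05
    frac_alpha: float = 0.05
    frac_neutral: float = 0.25
    frac_local: float = 0.10
    #: exponential-in-cos(theta) anisotropy of secondary-proton emission
    anisotropy_kappa: float = 2.0

    def __post_init__(self) -> None:
        fr = (self.frac_proton + self.frac_deuteron + self.frac_alpha
              + self.frac_neutral + self.frac_local)
        if not np.isclose(fr, 1.0):
            raise ValueError(f"nuclear energy fractions must sum to 1, got {fr}")
        if np.any(np.asarray(self.sigma_mm) < 0):
            raise ValueError("nuclear cross section must be nonnegative")

    def cross_section(self, energy_mev):
        """Macroscopic nonelastic cross section (mm^-1, water) at ``energy_mev``."""
        e = np.asarray(energy_mev, dtype=float)
        sig = np.interp(e, self.energy_grid_mev, self.sigma_mm,
                        left=0.0, right=float(self.sigma_mm[-1]))
        return np.where(e < self.threshold_mev, 0.0, sig)

    def mean_forward_cosine(self) -> float:
        """<cos theta> of the exp(kappa cos) secondary-proton emission law."""
        k = self.anisotropy_kappa
        return 1.0 / np.tanh(k) - 1.0 / k


#: Joules per MeV
MEV_TO_J = 1.602176634e-13

#: Laterally integrated dose per proton per unit stopping power in water:
#: Gy mm^2 per (MeV/mm), i.e. 1.602e-13 J/MeV divided by 1e-6 kg/mm^3.
GY_MM2_PER_MEV_PER_MM = MEV_TO_J / 1.0e-6
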