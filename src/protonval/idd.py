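"""Integrated depth-dose (IDD) curves for pristine proton pencil beams.

An IDD is the laterally integrated dose of a single pencil beam versus depth
in water.  Curves are built by 1D numerical transport using the same physics
primitives as the Monte Carlo engine:

* CSDA slowing down on the Bragg-Kleeman range-energy relation,
* Gaussian range straggling (Bohr) applied as a convolution,
* nonelastic nuclear interactions: primary fluence attenuation, local
  deposition of heavy-recoil/deuteron/alpha energy, escape of the neutral
  fraction, and a secondary-proton deposition kernel that accounts for the
  forward-peaked emission angle and a second interaction generation.

Because the analytical pencil-beam engine evaluates exactly these curves
while the Monte Carlo engine samples the same interaction model event by
event, the two engines agree closely in laterally homogeneous media; their
differences isolate the slab-geometry approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import physics
from .physics import NuclearModel

CLINICAL_ENERGY_RANGE = (70.0, 230.0)


@dataclass
class IDDCurve:
    """Laterally integrated depth dose of one pencil beam in water."""

    energy: float
    depth_grid: np.ndarray        # mm (water-equivalent depth)
    mev_per_mm: np.ndarray        # deposited energy density per proton
    protons_per_mu: float
    #: part of mev_per_mm deposited by secondary protons (wide lateral halo)
    mev_per_mm_secondary: np.ndarray | None = None

    @property
    def dose_per_mu(self) -> np.ndarray:
        """Gy mm^2 per MU versus depth."""
        return self.mev_per_mm * physics.GY_MM2_PER_MEV_PER_MM * self.protons_per_mu

    def __call__(self, depth_mm):
        """Linear interpolation of the per-MU curve (0 outside the grid)."""
        return np.interp(np.asarray(depth_mm, dtype=float), self.depth_grid,
                         self.dose_per_mu, left=0.0, right=0.0)

    def mev_per_mm_at(self, depth_mm):
        return np.interp(np.asarray(depth_mm, dtype=float), self.depth_grid,
                         self.mev_per_mm, left=0.0, right=0.0)

    def mev_per_mm_secondary_at(self, depth_mm):
        """Secondary-proton (halo) component; zero when nuclear is disabled."""
        if self.mev_per_mm_secondary is None:
            return np.zeros_like(np.asarray(depth_mm, dtype=float))
        return np.interp(np.asarray(depth_mm, dtype=float), self.depth_grid,
                         self.mev_per_mm_secondary, left=0.0, right=0.0)

    def distal_depth(self, level: float) -> float:
        """Distal depth (mm) where the curve falls to ``level`` x its maximum."""
        d = self.dose_per_mu
        ipk = int(np.argmax(d))
        target = level * d[ipk]
        tail = d[ipk:]
        below = np.nonzero(tail < target)[0]
        if below.size == 0:
            return float(self.depth_grid[-1])
        j = below[0] + ipk
        # linear crossing between j-1 and j
        d0, d1 = d[j - 1], d[j]
        z0, z1 = self.depth_grid[j - 1], self.depth_grid[j]
        if d0 == d1:
            return float(z0)
        return float(z0 + (d0 - target) / (d0 - d1) * (z1 - z0))


class IDDLibrary:
    """Caches IDD curves per energy, all built with one physics configuration."""

    def __init__(self, nuclear: NuclearModel | None = None,
                 include_nuclear: bool = True,
                 include_straggling: bool = True,
                 dz: float = 0.5,
                 protons_per_mu: float = 1.0e9,
                 alpha_mm: float = physics.ALPHA_MM,
                 p: float = physics.P_EXP,
                 bohr_var_mm: float = physics.BOHR_VAR_MM):
        self.nuclear = nuclear if nuclear is not None else NuclearModel()
        self.include_nuclear = include_nuclear
        self.include_straggling = include_straggling
        self.dz = float(dz)
        self.protons_per_mu = float(protons_per_mu)
        self.alpha_mm = alpha_mm
        self.p = p
        self.bohr_var_mm = bohr_var_mm
        self._cache: dict[float, IDDCurve] = {}
        self._kernels: dict[int, tuple[int, np.ndarray, float]] = {}
        # secondary-proton kernel energy grid (geometric spacing)
        self._kernel_energies = np.geomspace(self.nuclear.threshold_mev, 260.0, 28)

    # ---- 1D CSDA helpers --------------------------------------------------

    def _csda_profile(self, energy: float, nuclear_secondaries_local: bool):
        """Per-proton path profile of deposited energy density (MeV/mm).

        Returns (grid, deposit density, interaction density * E, fluence).
        With ``nuclear_secondaries_local`` the whole non-neutral interaction
        energy is deposited at the interaction site (used for the second
        secondary generation).
        """
        rng_mm = physics.range_from_energy(energy, self.alpha_mm, self.p)
        z = np.arange(0.0, float(rng_mm) + 2.0 * self.dz, self.dz)
        e_res = physics.energy_from_range(np.clip(rng_mm - z, 0.0, None),
                                          self.alpha_mm, self.p)
        # energy lost to ionization inside each bin, as residual-energy diffs
        d_ion = np.empty_like(z)
        d_ion[:-1] = (e_res[:-1] - e_res[1:]) / self.dz
        d_ion[-1] = e_res[-1] / self.dz
        if not self.include_nuclear:
            return z, d_ion, np.zeros_like(z), np.ones_like(z)
        sigma = self.nuclear.cross_section(e_res)
        # fluence surviving nonelastic interactions
        flu = np.exp(-np.concatenate([[0.0], np.cumsum(0.5 * (sigma[:-1] + sigma[1:]) * self.dz)]))[:z.size]
        n_int = flu * sigma                 # interactions per mm per proton
        deposit = flu * d_ion
        nm = self.nuclear
        if nuclear_secondaries_local:
            local_frac = 1.0 - nm.frac_neutral
        else:
            local_frac = nm.frac_local + nm.frac_deuteron + nm.frac_alpha
        deposit = deposit + n_int * e_res * local_frac
        return z, deposit, n_int * e_res, flu

    # ---- secondary-proton kernel -----------------------------------------

    def _secondary_kernel(self, idx: int):
        """Depth-deposition kernel of one secondary proton of kernel energy idx.

        Built by projecting the straight-path profile over the forward-peaked
        emission-angle distribution exp(kappa cos theta).  Returns
        (center_bin, energy-per-bin array, kernel energy).
        """
        if idx in self._kernels:
            return self._kernels[idx]
        es = float(self._kernel_energies[idx])
        s, dep, _, _ = self._csda_profile(es, nuclear_secondaries_local=True)
        # Gauss-Legendre nodes over cos(theta) in [-1, 1]
        mu, w = np.polynomial.legendre.leggauss(24)
        w = w * np.exp(self.nuclear.anisotropy_kappa * mu)
        w = w / w.sum()
        nfor = s.size
        kern = np.zeros(2 * nfor + 3)
        center = nfor + 1
        e_bin = dep * self.dz                       # MeV deposited per path bin
        for m, wm in zip(mu, w):
            # cloud-in-cell binning of the slant-projected path bins
            fj = center + s * m / self.dz
            j0 = np.floor(fj).astype(np.int64)
            fr = fj - j0
            np.add.at(kern, np.clip(j0, 0, kern.size - 1), wm * e_bin * (1 - fr))
            np.add.at(kern, np.clip(j0 + 1, 0, kern.size - 1), wm * e_bin * fr)
        kern = gaussian_filter1d(kern, 1.0, mode="constant")
        self._kernels[idx] = (center, kern, es)
        return self._kernels[idx]

    def _straggle_convolve(self, energy: float, z: np.ndarray,
                           deposit: np.ndarray) -> np.ndarray:
        """Depth-dependent Bohr straggling: each source bin is smeared with
        the depth spread accumulated up to that bin, sigma^2(z) =
        k_B * integral 1/S(E(z'))^2 dz', so the entrance stays sharp while
        the Bragg peak receives the full range straggling."""
        rng_mm = physics.range_from_energy(energy, self.alpha_mm, self.p)
        e_res = physics.energy_from_range(np.clip(rng_mm - z, 1e-3, None),
                                          self.alpha_mm, self.p)
        inv_s2 = 1.0 / physics.stopping_power_water(e_res, self.alpha_mm,
                                                    self.p) ** 2
        var = self.bohr_var_mm * np.cumsum(inv_s2) * self.dz
        var = np.minimum(var, physics.range_straggling_sigma(
            energy, self.alpha_mm, self.p, self.bohr_var_mm) ** 2)
        sig = np.sqrt(var)
        from scipy.special import erf
        out = np.zeros_like(deposit)
        inv_sqrt2 = 1.0 / np.sqrt(2.0)
        for j in range(deposit.size):
            dj = deposit[j]
            if dj <= 0:
                continue
            s = max(sig[j] if j < sig.size else sig[-1], 1e-4)
            half = int(np.ceil(4.0 * s / self.dz)) + 1
            lo = max(0, j - half)
            hi = min(deposit.size, j + half + 1)
            # integrate the Gaussian over each destination bin so the kernel
            # degrades smoothly to the identity as sigma -> 0
            edges = (np.arange(lo, hi + 1) - j - 0.5) * self.dz
            cdf = erf(edges / s * inv_sqrt2)
            g = 0.5 * (cdf[1:] - cdf[:-1])
            gsum = g.sum()
            if gsum > 0:
                out[lo:hi] += dj * g / gsum
        return out

    # ---- public -----------------------------------------------------------

    def curve(self, energy: float) -> IDDCurve:
        key = round(float(energy), 3)
        if key in self._cache:
            return self._cache[key]
        z, deposit, e_int, _ = self._csda_profile(float(energy),
                                                  nuclear_secondaries_local=False)
        secondary = np.zeros_like(deposit)
        if self.include_nuclear:
            rng_mm = physics.range_from_energy(energy, self.alpha_mm, self.p)
            e_res = physics.energy_from_range(np.clip(rng_mm - z, 0.0, None),
                                              self.alpha_mm, self.p)
            # pad so downstream secondary deposition fits
            pad = int(np.ceil(0.8 * z.size)) + 4
            total = np.concatenate([deposit, np.zeros(pad)])
            sec = np.zeros_like(total)
            fp = self.nuclear.frac_proton
            for i in range(z.size):
                if e_int[i] <= 0:
                    continue
                es = fp * e_res[i]
                if es < self.nuclear.threshold_mev / 2.0:
                    total[i] += e_int[i] * fp
                    continue
                # interpolate between the two bracketing kernel energies so
                # the secondary deposition varies smoothly with depth
                k1 = int(np.searchsorted(self._kernel_energies, es))
                k1 = min(max(k1, 1), self._kernel_energies.size - 1)
                k0 = k1 - 1
                e0k, e1k = self._kernel_energies[k0], self._kernel_energies[k1]
                w1 = float(np.clip((es - e0k) / (e1k - e0k), 0.0, 1.0))
                for kidx, wk in ((k0, 1.0 - w1), (k1, w1)):
                    if wk <= 0:
                        continue
                    center, kern, ek = self._secondary_kernel(kidx)
                    # secondaries per mm times dz, rescaled to conserve the
                    # actual secondary energy es (kernel built at ek)
                    amp = wk * (e_int[i] * fp * self.dz) / ek
                    lo = max(0, i - center)
                    hi = min(total.size, i - center + kern.size)
                    contrib = amp * kern[lo - (i - center):hi - (i - center)] \
                        / self.dz
                    total[lo:hi] += contrib
                    sec[lo:hi] += contrib
            deposit = total
            secondary = sec
            z = np.arange(deposit.size) * self.dz
        if self.include_straggling:
            deposit = self._straggle_convolve(float(energy), z, deposit)
            if self.include_nuclear:
                secondary = self._straggle_convolve(float(energy), z, secondary)
        curve = IDDCurve(float(energy), z, deposit, self.protons_per_mu,
                         mev_per_mm_secondary=secondary)
        self._cache[key] = curve
        return curve


    def curve_for_beamline(self, energy: float, beamline) -> IDDCurve:
        """IDD indexed by *phantom* WED for a beam behind a range shifter.

        The shifter is pure upstream WET: the curve is built at the pulled-back
        energy, convolved with the Bohr energy spread accumulated in the
        shifter (converted to a depth spread), and scaled by the primary
        survival probability against nonelastic interactions in the shifter.
        The Monte Carlo engine applies the identical pullback, energy spread
        and survival, so the two engines share one beamline model.
        """
        rs = float(beamline.range_shifter_wet)
        if rs <= 0:
            return self.curve(energy)
        key = (round(float(energy), 3), round(rs, 3))
        if key in self._cache:
            return self._cache[key]
        e_ph = beamline.energy_at_phantom(energy)
        base = self.curve(e_ph)
        mev = base.mev_per_mm.copy()
        sec = (base.mev_per_mm_secondary.copy()
               if base.mev_per_mm_secondary is not None else None)
        sig_e = np.sqrt(self.bohr_var_mm * rs)
        sig_z = sig_e / float(physics.stopping_power_water(e_ph, self.alpha_mm, self.p))
        if self.include_straggling and sig_z > 0:
            mev = gaussian_filter1d(mev, sig_z / self.dz, mode="constant")
            if sec is not None:
                sec = gaussian_filter1d(sec, sig_z / self.dz, mode="constant")
        surv = self.shifter_survival(energy, rs)
        mev = mev * surv
        if sec is not None:
            sec = sec * surv
        curve = IDDCurve(float(energy), base.depth_grid, mev, self.protons_per_mu,
                         mev_per_mm_secondary=sec)
        self._cache[key] = curve
        return curve

    def shifter_survival(self, energy: float, rs_wet: float) -> float:
        """Probability that a primary crosses the range shifter without a
        nonelastic interaction (secondaries made in the shifter are dropped)."""
        if not self.include_nuclear or rs_wet <= 0:
            return 1.0
        z = np.linspace(0.0, rs_wet, 64)
        rng_mm = physics.range_from_energy(energy, self.alpha_mm, self.p)
        e_res = physics.energy_from_range(np.clip(rng_mm - z, 1e-3, None),
                                          self.alpha_mm, self.p)
        return float(np.exp(-np.trapezoid(self.nuclear.cross_section(e_res), z)))


def bragg_idd(energy: float, depth_grid=None,
              library: IDDLibrary | None = None) -> IDDCurve:
    """Pristine Bragg curve for one machine energy.

    ``depth_grid`` (mm), when given, resamples the curve onto that grid.
    Energies outside the clinical range raise, naming the nearest available
    energy.
    """
    lo, hi = CLINICAL_ENERGY_RANGE
    if not (lo <= energy <= hi):
        nearest = lo if energy < lo else hi
        raise ValueError(f"energy {energy} MeV outside clinical range "
                         f"[{lo}, {hi}]; nearest available energy is {nearest}")
    lib = library if library is not None else IDDLibrary()
    curve = lib.curve(energy)
    if depth_grid is None:
        return curve
    depth_grid = np.asarray(depth_grid, dtype=float)
    mev = curve.mev_per_mm_at(depth_grid)
    return IDDCurve(curve.energy, depth_grid, mev, curve.protons_per_mu)
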