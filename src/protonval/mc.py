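"""Condensed-history Class II proton Monte Carlo on a voxel phantom.

Per history: a spot is sampled proportionally to its weight, the initial
lateral position is drawn from the spot's in-air Gaussian at the phantom
surface, and the proton is stepped through the voxel grid.  Each step is
limited by the next voxel boundary, a maximum fractional energy loss, and an
absolute cap of one voxel diagonal.  Along a step:

* the mean ionization loss comes from the parameterized stopping power
  (midpoint rule), with a Gaussian Bohr straggling fluctuation, deposited
  locally (delta electrons are assumed absorbed within the voxel);
* a Gaussian (Highland) multiple-scattering deflection is applied, the
  small-angle limit of Goudsmit-Saunderson theory;
* a nonelastic nuclear interaction may occur with probability
  ``1 - exp(-Sigma(E) * step)``; the incident energy is then split into a
  secondary proton (continues in Class II transport, forward-peaked
  direction), deuteron/alpha fragments (straight-line CSDA deposition),
  neutrals (energy removed and tallied as escaped), and a locally absorbed
  heavy-recoil share.

Statistical uncertainty uses the batch method: per-voxel dose is accumulated
over independent batches and the relative standard error per voxel is the
batch spread over sqrt(n_batches).  The default stopping rule halts the run
once the mean relative uncertainty over voxels above half the maximum dose
drops below the target (0.5 %).

Primary sampling is stratified by default (deterministic spot allocation
with stochastic remainder rounding plus Latin-hypercube lateral positions
within each batch), a standard variance-reduction technique that leaves the
batch estimator unbiased because batches remain independent and identically
distributed.  ``sampling="iid"`` disables it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import ndtri

from . import physics
from .beamline import PBSPlan, beam_frame
from .dose import DoseCube
from .idd import IDDLibrary
from .phantom import VoxelPhantom

logger = logging.getLogger(__name__)

E_CUTOFF_MEV = 1.0          # transport cutoff; residual deposited locally
MAX_FRAC_ELOSS = 0.08       # max fractional energy loss per step (midpoint rule)
_ETAB_MAX = 260.0
_ETAB_N = 2048


@dataclass
class RunStats:
    """Bookkeeping of one Monte Carlo run."""

    histories: int
    batches: int
    seed: int
    aggregate_uncertainty: float      # mean rel. sigma over voxels > 50% max
    target_uncertainty: float | None
    reached_target: bool
    injected_mev: float
    deposited_mev: float
    escaped_mev: float

    @property
    def energy_balance_error(self) -> float:
        """|deposited + escaped - injected| / injected."""
        if self.injected_mev == 0:
            return 0.0
        return abs(self.deposited_mev + self.escaped_mev - self.injected_mev) \
            / self.injected_mev

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self) | {
            "energy_balance_error": self.energy_balance_error}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# sampling primitives (the kernel below inlines the same distributions)
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """A particle in flight; used by the standalone sampling API."""

    position: np.ndarray                 # mm
    direction: np.ndarray                # unit vector
    kinetic_energy: float                # MeV
    species: str = "proton"              # proton | deuteron | alpha
    statistical_weight: float = 1.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n
        if self.kinetic_energy < 0:
            raise ValueError("kinetic_energy must be >= 0")


def sample_scattering_angle(energy_mev: float, step_wet: float, material=None,
                            rng: np.random.Generator | None = None):
    """Gaussian (Highland) polar deflections for one condensed step.

    Returns (theta_x, theta_y), the two projected scattering angles in
    radians; the azimuth is implicit in their independence.  A zero step
    gives exactly zero deflection.  ``material`` supplies the radiation
    length (water by default); the step is given in water-equivalent mm and
    converted to a path length in the material through its RSP.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if step_wet < 0:
        raise ValueError("step_wet must be >= 0")
    if step_wet == 0.0:
        return 0.0, 0.0
    if material is None:
        x0 = physics.WATER_X0_MM
        length = step_wet
    else:
        x0 = material.x0_mm
        length = step_wet / max(material.rsp, 1e-6)
    c = physics.highland_log_correction()
    sigma = (14.1 / physics.momentum_velocity(energy_mev))         * np.sqrt(length / x0) * c
    return float(sigma * rng.standard_normal()),         float(sigma * rng.standard_normal())


def sample_energy_straggling(mean_loss: float, step_wet: float,
                             rng: np.random.Generator | None = None,
                             kinetic_energy: float | None = None) -> float:
    """Actual energy loss: Gaussian around the mean with Bohr variance
    proportional to the water-equivalent step, truncated to
    [0, kinetic_energy]."""
    rng = rng if rng is not None else np.random.default_rng()
    if mean_loss < 0:
        raise ValueError("mean_loss must be >= 0")
    if step_wet == 0.0:
        return 0.0
    loss = mean_loss + np.sqrt(physics.BOHR_VAR_MM * step_wet)         * rng.standard_normal()
    hi = kinetic_energy if kinetic_energy is not None else np.inf
    return float(np.clip(loss, 0.0, hi))


def sample_nuclear_interaction(state: ParticleState, step_mm: float,
                               material=None,
                               nuclear: physics.NuclearModel | None = None,
                               rng: np.random.Generator | None = None):
    """Nonelastic interaction over a step, or None.

    Occurs with probability ``1 - exp(-Sigma(E) * scale * step)``.  On
    interaction the incident kinetic energy E is partitioned exactly:
    a secondary proton (Class II transport continues), deuteron and alpha
    fragments (straight-line CSDA deposition), neutrals (energy leaves the
    simulation) and a locally absorbed heavy-recoil share.  Only protons
    interact; fragments do not re-interact.
    """
    if state.species != "proton":
        return None
    rng = rng if rng is not None else np.random.default_rng()
    nm = nuclear if nuclear is not None else physics.NuclearModel()
    scale = material.nuclear_scale if material is not None else 1.0
    e = state.kinetic_energy
    sigma = float(nm.cross_section(e)) * scale
    if sigma <= 0:
        return None
    if rng.random() >= -np.expm1(-sigma * step_mm):
        return None
    return {
        "incident_energy": e,
        "secondary_proton": e * nm.frac_proton,
        "deuteron": e * nm.frac_deuteron,
        "alpha": e * nm.frac_alpha,
        "neutral": e * nm.frac_neutral,
        "local": e * nm.frac_local,
    }


# ---------------------------------------------------------------------------
# transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mix64(z):
    """splitmix64 step for seeding the per-batch RNG state."""
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xoro(state):
    """xoroshiro128+ uniform in [0, 1)."""
    s0 = state[0]
    s1 = state[1]
    r = (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s0
    state[0] = (((s0 << np.uint64(55)) | (s0 >> np.uint64(9)))
                ^ s1 ^ ((s1 << np.uint64(14)) & np.uint64(0xFFFFFFFFFFFFFFFF))) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    state[1] = ((s1 << np.uint64(36)) | (s1 >> np.uint64(28))) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (r >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, fastmath=True)
def _transport_batch(mat, rsp_tab, nuc_tab, invx0_tab, lo, sp,
                     px, py, pz, ux, uy, uz, e0,
                     e_tab_de, s_tab, sig_tab, kth_tab,
                     k_bohr, e_cutoff, max_frac, max_step,
                     frac_p, frac_d, frac_a, frac_n, frac_local, kappa,
                     alpha_mm, p_exp, edep, seed,
                     nrep, bx, by, sig_h, rec):
    """Transport one batch of prepared primaries; tally energy (MeV) in edep.

    Returns (deposited, escaped) MeV.  Steps are grouped into macro-steps of
    up to three voxel crossings within one material (Gaussian scattering and
    straggling variances are strictly additive, so the grouping changes no
    physics moments).  Gaussian variates come from a cached Box-Muller
    transform over a xoroshiro128+ stream; the nuclear interaction point is
    sampled by exponential optical depth.

    With ``nrep > 0`` (valid only for +z beams in laterally homogeneous
    phantoms) each history's energy deposits are recorded relative to its
    entry point and replayed at ``nrep`` fresh lateral samples of the same
    spot Gaussian with weight 1/nrep — track-repeating variance reduction
    that leaves per-batch expectations unbiased.
    """
    state = np.empty(2, dtype=np.uint64)
    state[0] = _mix64(np.uint64(seed))
    state[1] = _mix64(state[0] ^ np.uint64(0xDEADBEEFCAFEF00D))
    have_spare = False
    spare = 0.0

    nx, ny, nz = mat.shape
    hix = lo[0] + nx * sp[0]
    hiy = lo[1] + ny * sp[1]
    hiz = lo[2] + nz * sp[2]
    deposited = 0.0
    escaped = 0.0
    expk = np.exp(kappa)
    expmk = np.exp(-kappa)
    ntab = s_tab.shape[0]
    seg_px = np.empty(4); seg_py = np.empty(4); seg_pz = np.empty(4)
    seg_i = np.empty(4, dtype=np.int64)
    seg_j = np.empty(4, dtype=np.int64)
    seg_k = np.empty(4, dtype=np.int64)
    seg_l = np.empty(4)
    cap = rec.shape[0]

    for h in range(px.shape[0]):
        x = px[h]; y = py[h]; z = pz[h]
        vx = ux[h]; vy = uy[h]; vz = uz[h]
        e = e0[h]
        sx0 = x; sy0 = y
        nr = 0

        # advance a particle starting outside the grid to the bounding box
        tmin = 0.0
        tmax = 1.0e30
        miss = False
        for a in range(3):
            if a == 0:
                pa = x; va = vx; la = lo[0]; ha = hix
            elif a == 1:
                pa = y; va = vy; la = lo[1]; ha = hiy
            else:
                pa = z; va = vz; la = lo[2]; ha = hiz
            if abs(va) < 1e-12:
                if pa < la or pa >= ha:
                    miss = True
                    break
            else:
                t1 = (la - pa) / va
                t2 = (ha - pa) / va
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if miss or tmin >= tmax:
            escaped += e
            continue
        if tmin > 0.0:
            x += (tmin + 1e-6) * vx
            y += (tmin + 1e-6) * vy
            z += (tmin + 1e-6) * vz

        # optical depth to the next nuclear interaction
        tau = -np.log(1.0 - _xoro(state))

        while True:
            if e <= e_cutoff:
                if nrep > 0 and nr < cap:
                    rec[nr, 0] = x - sx0; rec[nr, 1] = y - sy0
                    rec[nr, 2] = z; rec[nr, 3] = e
                    nr += 1
                else:
                    ix = int(np.floor((x - lo[0]) / sp[0]))
                    iy = int(np.floor((y - lo[1]) / sp[1]))
                    iz = int(np.floor((z - lo[2]) / sp[2]))
                    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                        edep[ix, iy, iz] += e
                        deposited += e
                    else:
                        escaped += e
                break
            ix = int(np.floor((x - lo[0]) / sp[0]))
            iy = int(np.floor((y - lo[1]) / sp[1]))
            iz = int(np.floor((z - lo[2]) / sp[2]))
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += e
                break
            m0 = mat[ix, iy, iz]
            rsp = rsp_tab[m0]

            # water stopping power at the current energy (table lookup)
            fi = e / e_tab_de
            i0 = int(fi)
            if i0 >= ntab - 1:
                i0 = ntab - 2
            fr = fi - i0
            s_w = s_tab[i0] * (1.0 - fr) + s_tab[i0 + 1] * fr
            sig_w = sig_tab[i0] * (1.0 - fr) + sig_tab[i0 + 1] * fr

            # macro-step budget: energy cap and absolute cap
            budget = max_step
            if rsp > 1e-6:
                capE = max_frac * e / (s_w * rsp)
                if capE < budget:
                    budget = capE

            # collect up to 3 same-material sub-segments along v
            nseg = 0
            total = 0.0
            cx = x; cy = y; cz = z
            jx = ix; jy = iy; jz = iz
            exited = False
            while nseg < 3:
                t = budget - total
                if vx > 1e-12:
                    tt = ((lo[0] + (jx + 1) * sp[0]) - cx) / vx
                    if tt < t: t = tt
                elif vx < -1e-12:
                    tt = ((lo[0] + jx * sp[0]) - cx) / vx
                    if tt < t: t = tt
                if vy > 1e-12:
                    tt = ((lo[1] + (jy + 1) * sp[1]) - cy) / vy
                    if tt < t: t = tt
                elif vy < -1e-12:
                    tt = ((lo[1] + jy * sp[1]) - cy) / vy
                    if tt < t: t = tt
                if vz > 1e-12:
                    tt = ((lo[2] + (jz + 1) * sp[2]) - cz) / vz
                    if tt < t: t = tt
                elif vz < -1e-12:
                    tt = ((lo[2] + jz * sp[2]) - cz) / vz
                    if tt < t: t = tt
                t += 1e-4
                seg_px[nseg] = cx; seg_py[nseg] = cy; seg_pz[nseg] = cz
                seg_i[nseg] = jx; seg_j[nseg] = jy; seg_k[nseg] = jz
                seg_l[nseg] = t
                nseg += 1
                cx += t * vx; cy += t * vy; cz += t * vz
                total += t
                if total >= budget:
                    break
                jx = int(np.floor((cx - lo[0]) / sp[0]))
                jy = int(np.floor((cy - lo[1]) / sp[1]))
                jz = int(np.floor((cz - lo[2]) / sp[2]))
                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    exited = True
                    break
                if mat[jx, jy, jz] != m0:
                    break
            wet = total * rsp

            # midpoint mean energy loss over the macro-step
            de1 = s_w * wet
            emid = e - 0.5 * de1
            if emid < 0.25 * e:
                emid = 0.25 * e
            fi = emid / e_tab_de
            i0 = int(fi)
            if i0 >= ntab - 1:
                i0 = ntab - 2
            fr = fi - i0
            mean_loss = (s_tab[i0] * (1.0 - fr) + s_tab[i0 + 1] * fr) * wet
            loss = mean_loss
            if wet > 0.0:
                if have_spare:
                    g = spare
                    have_spare = False
                else:
                    r1 = _xoro(state)
                    r2 = _xoro(state)
                    magbm = np.sqrt(-2.0 * np.log(1.0 - r1))
                    angbm = 6.283185307179586 * r2
                    g = magbm * np.cos(angbm)
                    spare = magbm * np.sin(angbm)
                    have_spare = True
                loss += np.sqrt(k_bohr * wet) * g
            if loss < 0.0:
                loss = 0.0
            if loss > e:
                loss = e

            dtau = sig_w * nuc_tab[m0] * total
            if dtau > 0.0 and tau <= dtau:
                # nuclear interaction at path fraction f along the macro-step
                f = tau / dtau
                s_int = f * total
                part = loss * f
                # ionization up to the interaction point, split by segment
                run = 0.0
                for q in range(nseg):
                    l0 = run
                    run += seg_l[q]
                    covered = min(s_int, run) - l0
                    if covered <= 0.0:
                        break
                    share = loss * covered / total
                    if nrep > 0 and nr < cap:
                        mx = seg_px[q] + 0.5 * covered * vx
                        my = seg_py[q] + 0.5 * covered * vy
                        mz = seg_pz[q] + 0.5 * covered * vz
                        rec[nr, 0] = mx - sx0; rec[nr, 1] = my - sy0
                        rec[nr, 2] = mz; rec[nr, 3] = share
                        nr += 1
                    else:
                        edep[seg_i[q], seg_j[q], seg_k[q]] += share
                        deposited += share
                    if s_int <= run:
                        break
                x += s_int * vx
                y += s_int * vy
                z += s_int * vz
                ei = e - part
                if nrep > 0 and nr < cap:
                    rec[nr, 0] = x - sx0; rec[nr, 1] = y - sy0
                    rec[nr, 2] = z; rec[nr, 3] = ei * frac_local
                    nr += 1
                else:
                    kx = int(np.floor((x - lo[0]) / sp[0]))
                    ky = int(np.floor((y - lo[1]) / sp[1]))
                    kz = int(np.floor((z - lo[2]) / sp[2]))
                    if 0 <= kx < nx and 0 <= ky < ny and 0 <= kz < nz:
                        edep[kx, ky, kz] += ei * frac_local
                        deposited += ei * frac_local
                    else:
                        escaped += ei * frac_local
                escaped += ei * frac_n
                pn = np.sqrt(vx * vx + vy * vy)
                if pn < 1e-9:
                    t1x = 1.0; t1y = 0.0; t1z = 0.0
                    t2x = 0.0; t2y = 1.0; t2z = 0.0
                else:
                    t1x = vy / pn; t1y = -vx / pn; t1z = 0.0
                    t2x = vy * t1z - vz * t1y
                    t2y = vz * t1x - vx * t1z
                    t2z = vx * t1y - vy * t1x
                # deuteron / alpha fragments: straight-line CSDA deposition
                for frag in range(2):
                    if frag == 0:
                        ef = ei * frac_d
                        rng_f = 2.0 * alpha_mm * (0.5 * ef) ** p_exp
                    else:
                        ef = ei * frac_a
                        rng_f = alpha_mm * (0.25 * ef) ** p_exp
                    if ef <= 0.0:
                        continue
                    mu = np.log(expmk + _xoro(state) * (expk - expmk)) / kappa
                    st = np.sqrt(max(1.0 - mu * mu, 0.0))
                    phi = 6.283185307179586 * _xoro(state)
                    cp = np.cos(phi); sp_ = np.sin(phi)
                    fx = mu * vx + st * (cp * t1x + sp_ * t2x)
                    fy = mu * vy + st * (cp * t1y + sp_ * t2y)
                    fz = mu * vz + st * (cp * t1z + sp_ * t2z)
                    rloc = rsp
                    if rloc < 1e-3:
                        rloc = 1e-3
                    rng_eff = rng_f / rloc
                    nsub = int(rng_eff / (0.5 * sp[0])) + 1
                    dsub = rng_eff / nsub
                    dei = ef / nsub
                    fxp = x; fyp = y; fzp = z
                    for q in range(nsub):
                        fxp += dsub * fx; fyp += dsub * fy; fzp += dsub * fz
                        if nrep > 0 and nr < cap:
                            rec[nr, 0] = fxp - sx0; rec[nr, 1] = fyp - sy0
                            rec[nr, 2] = fzp; rec[nr, 3] = dei
                            nr += 1
                        else:
                            kxq = int(np.floor((fxp - lo[0]) / sp[0]))
                            kyq = int(np.floor((fyp - lo[1]) / sp[1]))
                            kzq = int(np.floor((fzp - lo[2]) / sp[2]))
                            if 0 <= kxq < nx and 0 <= kyq < ny and 0 <= kzq < nz:
                                edep[kxq, kyq, kzq] += dei
                                deposited += dei
                            else:
                                escaped += dei
                # secondary proton continues in Class II transport
                e = ei * frac_p
                mu = np.log(expmk + _xoro(state) * (expk - expmk)) / kappa
                st = np.sqrt(max(1.0 - mu * mu, 0.0))
                phi = 6.283185307179586 * _xoro(state)
                cp = np.cos(phi); sp_ = np.sin(phi)
                nvx = mu * vx + st * (cp * t1x + sp_ * t2x)
                nvy = mu * vy + st * (cp * t1y + sp_ * t2y)
                nvz = mu * vz + st * (cp * t1z + sp_ * t2z)
                nn = np.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
                vx = nvx / nn; vy = nvy / nn; vz = nvz / nn
                tau = -np.log(1.0 - _xoro(state))
                continue
            tau -= dtau

            # ordinary macro-step: deposit per sub-segment, then scatter once
            if nrep > 0:
                for q in range(nseg):
                    if nr < cap:
                        mx = seg_px[q] + 0.5 * seg_l[q] * vx
                        my = seg_py[q] + 0.5 * seg_l[q] * vy
                        mz = seg_pz[q] + 0.5 * seg_l[q] * vz
                        rec[nr, 0] = mx - sx0; rec[nr, 1] = my - sy0
                        rec[nr, 2] = mz; rec[nr, 3] = loss * seg_l[q] / total
                        nr += 1
            else:
                for q in range(nseg):
                    share = loss * seg_l[q] / total
                    edep[seg_i[q], seg_j[q], seg_k[q]] += share
                    deposited += share
            e -= loss
            x = cx; y = cy; z = cz
            if exited:
                escaped += e
                break
            if wet > 0.0 and e > e_cutoff:
                fi = e / e_tab_de
                i0 = int(fi)
                if i0 >= ntab - 1:
                    i0 = ntab - 2
                fr = fi - i0
                kth = kth_tab[i0] * (1.0 - fr) + kth_tab[i0 + 1] * fr
                sg = np.sqrt(kth * total * invx0_tab[m0])
                if have_spare:
                    g1 = spare
                    have_spare = False
                else:
                    r1 = _xoro(state)
                    r2 = _xoro(state)
                    magbm = np.sqrt(-2.0 * np.log(1.0 - r1))
                    angbm = 6.283185307179586 * r2
                    g1 = magbm * np.cos(angbm)
                    spare = magbm * np.sin(angbm)
                    have_spare = True
                if have_spare:
                    g2 = spare
                    have_spare = False
                else:
                    r1 = _xoro(state)
                    r2 = _xoro(state)
                    magbm = np.sqrt(-2.0 * np.log(1.0 - r1))
                    angbm = 6.283185307179586 * r2
                    g2 = magbm * np.cos(angbm)
                    spare = magbm * np.sin(angbm)
                    have_spare = True
                thx = sg * g1
                thy = sg * g2
                pn = np.sqrt(vx * vx + vy * vy)
                if pn < 1e-9:
                    t1x = 1.0; t1y = 0.0; t1z = 0.0
                    t2x = 0.0; t2y = 1.0; t2z = 0.0
                else:
                    t1x = vy / pn; t1y = -vx / pn; t1z = 0.0
                    t2x = vy * t1z - vz * t1y
                    t2y = vz * t1x - vx * t1z
                    t2z = vx * t1y - vy * t1x
                nvx = vx + thx * t1x + thy * t2x
                nvy = vy + thx * t1y + thy * t2y
                nvz = vz + thx * t1z + thy * t2z
                nn = np.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
                vx = nvx / nn; vy = nvy / nn; vz = nvz / nn

        # replay the recorded deposits at fresh lateral samples of the spot
        if nrep > 0 and nr > 0:
            winv = 1.0 / nrep
            for r in range(nrep):
                if have_spare:
                    g1 = spare
                    have_spare = False
                else:
                    r1 = _xoro(state)
                    r2 = _xoro(state)
                    magbm = np.sqrt(-2.0 * np.log(1.0 - r1))
                    angbm = 6.283185307179586 * r2
                    g1 = magbm * np.cos(angbm)
                    spare = magbm * np.sin(angbm)
                    have_spare = True
                if have_spare:
                    g2 = spare
                    have_spare = False
                else:
                    r1 = _xoro(state)
                    r2 = _xoro(state)
                    magbm = np.sqrt(-2.0 * np.log(1.0 - r1))
                    angbm = 6.283185307179586 * r2
                    g2 = magbm * np.cos(angbm)
                    spare = magbm * np.sin(angbm)
                    have_spare = True
                ox = bx[h] + sig_h[h] * g1
                oy = by[h] + sig_h[h] * g2
                for q in range(nr):
                    qx = ox + rec[q, 0]
                    qy = oy + rec[q, 1]
                    qz = rec[q, 2]
                    qe = rec[q, 3] * winv
                    kx = int(np.floor((qx - lo[0]) / sp[0]))
                    ky = int(np.floor((qy - lo[1]) / sp[1]))
                    kz = int(np.floor((qz - lo[2]) / sp[2]))
                    if 0 <= kx < nx and 0 <= ky < ny and 0 <= kz < nz:
                        edep[kx, ky, kz] += qe
                        deposited += qe
                    else:
                        escaped += qe
    return deposited, escaped


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _energy_tables(nuclear: physics.NuclearModel):
    de = _ETAB_MAX / (_ETAB_N - 1)
    e = np.maximum(np.arange(_ETAB_N) * de, 1e-3)
    s_tab = physics.stopping_power_water(e)
    sig_tab = np.asarray(nuclear.cross_section(e))
    c = physics.highland_log_correction()
    kth_tab = (14.1 * c / physics.momentum_velocity(e)) ** 2
    return de, s_tab, sig_tab, kth_tab


class _SpotSampler:
    """Prepares per-history primaries (position, direction, energy) per batch."""

    def __init__(self, plan: PBSPlan, phantom: VoxelPhantom,
                 idd_library: IDDLibrary, sampling: str):
        self.sampling = sampling
        lo = phantom.lower_corner()
        hi = phantom.upper_corner()
        corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                            for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        base, dirs, sig, emean, esig, w = [], [], [], [], [], []
        for beam in plan.beams:
            e1, e2, d = beam_frame(beam.direction)
            w_entry = float((corners @ d).min()) - 1.0
            bl = beam.beamline
            for layer in beam.layers:
                if bl.range_shifter_wet > 0:
                    e_ph = bl.energy_at_phantom(layer.energy)
                    es = np.sqrt(physics.BOHR_VAR_MM * bl.range_shifter_wet)
                    surv = idd_library.shifter_survival(layer.energy,
                                                        bl.range_shifter_wet)
                else:
                    e_ph, es, surv = layer.energy, 0.0, 1.0
                s_air = bl.spot_sigma_air(layer.energy)
                for s in layer.spots:
                    if s.weight <= 0:
                        continue
                    base.append(s.x * e1 + s.y * e2 + w_entry * d)
                    dirs.append(d)
                    sig.append(s_air)
                    emean.append(e_ph)
                    esig.append(es)
                    w.append(s.weight * surv)
        if not w:
            raise ValueError("plan has zero total weight")
        self.base = np.array(base)
        self.dirs = np.array(dirs)
        self.e1 = np.array([beam_frame(d)[0] for d in self.dirs])
        self.e2 = np.array([beam_frame(d)[1] for d in self.dirs])
        self.sigma = np.array(sig)
        self.emean = np.array(emean)
        self.esigma = np.array(esig)
        self.weights = np.array(w)
        self.total_weight = float(self.weights.sum())
        self.prob = self.weights / self.total_weight

    def batch(self, n: int, rng: np.random.Generator):
        if self.sampling == "stratified":
            counts = np.floor(self.prob * n).astype(np.int64)
            resid = self.prob * n - counts
            counts += (rng.random(resid.size) < resid).astype(np.int64)
            diff = n - int(counts.sum())
            if diff != 0:
                adj = rng.choice(self.prob.size, size=abs(diff), p=self.prob)
                np.add.at(counts, adj, 1 if diff > 0 else -1)
                counts = np.clip(counts, 0, None)
                n = int(counts.sum())
            ids = np.repeat(np.arange(self.prob.size), counts)
            # jittered 2D stratification of the lateral Gaussian per spot
            u1 = np.empty(n)
            u2 = np.empty(n)
            pos = 0
            for c in counts[counts > 0]:
                k = int(np.sqrt(c))
                ns = k * k
                if k >= 2:
                    gi, gj = np.divmod(np.arange(ns), k)
                    u1[pos:pos + ns] = (gi + rng.random(ns)) / k
                    u2[pos:pos + ns] = (gj + rng.random(ns)) / k
                    if c > ns:
                        u1[pos + ns:pos + c] = rng.random(c - ns)
                        u2[pos + ns:pos + c] = rng.random(c - ns)
                else:
                    u1[pos:pos + c] = rng.random(c)
                    u2[pos:pos + c] = rng.random(c)
                pos += c
        else:
            ids = rng.choice(self.prob.size, size=n, p=self.prob)
            u1 = rng.random(n)
            u2 = rng.random(n)
        g1 = ndtri(np.clip(u1, 1e-12, 1 - 1e-12))
        g2 = ndtri(np.clip(u2, 1e-12, 1 - 1e-12))
        pos3 = (self.base[ids]
                + (self.sigma[ids] * g1)[:, None] * self.e1[ids]
                + (self.sigma[ids] * g2)[:, None] * self.e2[ids])
        e0 = self.emean[ids] + self.esigma[ids] * rng.standard_normal(n)
        e0 = np.clip(e0, 1.0, None)
        return pos3, self.dirs[ids], e0, ids


def transport(plan: PBSPlan, phantom: VoxelPhantom, grid_spacing: float,
              histories: int | None = None,
              uncertainty_target: float | None = 0.005,
              seed: int = 0,
              batch_histories: int = 500_000,
              min_batches: int = 10,
              max_histories: int = 400_000_000,
              sampling: str = "stratified",
              lateral_replay: int = 0,
              nuclear: physics.NuclearModel | None = None,
              idd_library: IDDLibrary | None = None,
              e_cutoff: float = E_CUTOFF_MEV,
              max_frac_eloss: float = MAX_FRAC_ELOSS,
              ) -> tuple[DoseCube, RunStats]:
    """Run the Monte Carlo engine and return (DoseCube, RunStats).

    Exactly one stopping criterion applies: ``histories`` (split into
    ``min_batches`` x 2 batches) or ``uncertainty_target`` (default 0.5 %%
    mean relative uncertainty over voxels above half the maximum dose).

    ``lateral_replay=K`` enables track-repeating variance reduction: each
    history's deposits are replayed at K fresh lateral samples of its spot
    Gaussian (weight 1/K).  Only valid for +z beams in phantoms that are
    laterally homogeneous over the field, e.g. slab stacks.
    """
    if plan.total_mu <= 0:
        raise ValueError("plan has zero total MU")
    nuc = nuclear if nuclear is not None else physics.NuclearModel()
    lib = idd_library if idd_library is not None else IDDLibrary(nuclear=nuc)
    gs = float(grid_spacing)

    # resample the phantom material grid onto the dose grid if needed
    phantom = phantom.resampled(gs)
    mat = np.ascontiguousarray(phantom.material_index.astype(np.int16))
    lo = phantom.lower_corner()
    sp = np.array([gs, gs, gs])
    shape = mat.shape

    rsp_tab = phantom.materials.rsp_table()
    nuc_tab = phantom.materials.nuclear_table()
    invx0_tab = 1.0 / phantom.materials.x0_table()
    dens_tab = phantom.materials.density_table()
    de, s_tab, sig_tab, kth_tab = _energy_tables(nuc)
    max_step = float(np.sqrt(3.0) * gs)

    sampler = _SpotSampler(plan, phantom, lib, sampling)
    if lateral_replay > 0:
        for beam in plan.beams:
            if not np.allclose(beam.direction, [0.0, 0.0, 1.0], atol=1e-9):
                raise ValueError("lateral_replay requires +z beams")
    rec_buf = np.empty((8192 if lateral_replay > 0 else 1, 4))
    total_protons = plan.beams[0].beamline.protons_per_mu * sampler.total_weight
    mass = dens_tab[mat] * gs ** 3 * 1.0e-6          # kg per voxel
    mass = np.maximum(mass, 1e-30)

    if histories is not None:
        n_batches_fixed = 2 * min_batches
        batch_histories = max(int(np.ceil(histories / n_batches_fixed)), 1)
        max_total = batch_histories * n_batches_fixed
        uncertainty_target = None
    else:
        max_total = max_histories

    rng_master = np.random.default_rng(seed)
    dose_sum = np.zeros(shape)
    dose_sq = np.zeros(shape)
    edep = np.zeros(shape)
    nb = 0
    n_done = 0
    injected = deposited = escaped = 0.0
    agg = np.inf
    reached = False

    while n_done < max_total:
        pos, dirs, e0, ids = sampler.batch(batch_histories, rng_master)
        injected += float(e0.sum())
        edep[:] = 0.0
        kseed = int(rng_master.integers(0, 2 ** 31 - 1))
        dep, esc = _transport_batch(
            mat, rsp_tab, nuc_tab, invx0_tab, lo.astype(float), sp,
            np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
            np.ascontiguousarray(pos[:, 2]),
            np.ascontiguousarray(dirs[:, 0]), np.ascontiguousarray(dirs[:, 1]),
            np.ascontiguousarray(dirs[:, 2]), np.ascontiguousarray(e0),
            de, s_tab, sig_tab, kth_tab,
            physics.BOHR_VAR_MM, e_cutoff, max_frac_eloss, max_step,
            nuc.frac_proton, nuc.frac_deuteron, nuc.frac_alpha,
            nuc.frac_neutral, nuc.frac_local, nuc.anisotropy_kappa,
            physics.ALPHA_MM, physics.P_EXP, edep, kseed,
            lateral_replay, np.ascontiguousarray(sampler.base[ids, 0]),
            np.ascontiguousarray(sampler.base[ids, 1]),
            np.ascontiguousarray(sampler.sigma[ids]), rec_buf)
        deposited += dep
        escaped += esc
        # convert this batch's energy tally to Gy for the full plan
        w_hist = total_protons / batch_histories * physics.MEV_TO_J
        batch_gy = edep * (w_hist / mass)
        dose_sum += batch_gy
        dose_sq += batch_gy ** 2
        nb += 1
        n_done += batch_histories

        if uncertainty_target is not None and nb >= min_batches:
            agg = _aggregate_uncertainty(dose_sum, dose_sq, nb)
            if agg <= uncertainty_target:
                reached = True
                break

    mean = dose_sum / nb
    rel = _relative_uncertainty(dose_sum, dose_sq, nb)
    agg = _aggregate_uncertainty(dose_sum, dose_sq, nb)
    if uncertainty_target is not None and not reached:
        logger.warning("uncertainty target %.3g not reached (%.3g after %d "
                       "histories); partial result flagged",
                       uncertainty_target, agg, n_done)
    cube = DoseCube(dose=np.clip(mean, 0.0, None), spacing=sp,
                    origin=lo + gs / 2.0, engine_tag="mc",
                    relative_uncertainty=rel)
    stats = RunStats(histories=n_done, batches=nb, seed=seed,
                     aggregate_uncertainty=float(agg),
                     target_uncertainty=uncertainty_target,
                     reached_target=bool(reached or uncertainty_target is None),
                     injected_mev=injected, deposited_mev=deposited,
                     escaped_mev=escaped)
    return cube, stats


def _relative_uncertainty(dose_sum, dose_sq, nb) -> np.ndarray:
    mean = dose_sum / nb
    var = np.clip(dose_sq / nb - mean ** 2, 0.0, None) / max(nb - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / np.where(mean > 0, mean, 1.0), 0.0)
    return rel


def _aggregate_uncertainty(dose_sum, dose_sq, nb) -> float:
    """Mean relative standard error over voxels above half the max dose."""
    mean = dose_sum / nb
    dmax = mean.max()
    if dmax <= 0:
        return np.inf
    sel = mean > 0.5 * dmax
    rel = _relative_uncertainty(dose_sum, dose_sq, nb)
    return float(rel[sel].mean())


def compute_dose_mc(plan: PBSPlan, phantom: VoxelPhantom, grid_spacing: float,
                    **kwargs) -> DoseCube:
    """Convenience wrapper returning only the dose cube."""
    cube, _ = transport(plan, phantom, grid_spacing, **kwargs)
    return cube
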