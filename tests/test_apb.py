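"""Analytical pencil-beam engine: factorization, lateral spread, slab
blindness, linearity and normalization conservation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from protonval import physics
from protonval.apb import compute_dose_apb
from protonval.beamline import BeamLineConfig
from protonval.idd import IDDLibrary
from protonval.phantom import build_slab_phantom
from tests.conftest import single_spot_plan


@pytest.fixture(scope="module")
def plain_library():
    return IDDLibrary()


@pytest.fixture(scope="module")
def no_nuclear_library():
    return IDDLibrary(include_nuclear=False)


def test_central_axis_proportional_to_idd(plain_library, water_phantom,
                                          spot_plan_150):
    """Dividing out the lateral Gaussian peak must recover the IDD shape."""
    cube = compute_dose_apb(spot_plan_150, water_phantom, 2.0,
                            idd_library=plain_library, secondary_halo=False)
    bl = spot_plan_150.beams[0].beamline
    curve = plain_library.curve(150.0)
    sigma_air = bl.spot_sigma_air(150.0)
    ic = cube.shape[0] // 2
    z = cube.axis_centers(2)
    axis = cube.dose[ic, ic, :]
    idd = curve(z) * bl.protons_per_mu / plain_library.protons_per_mu
    sel = idd > 0.05 * idd.max()
    # recovered sigma^2 from the ratio, then verify proportionality
    ratio = axis[sel] * 2 * np.pi / idd[sel]       # = 1 / sigma^2(z)
    sig2 = 1.0 / ratio
    assert np.all(np.diff(sig2) > -1e-9)           # grows with depth
    assert sig2[0] == pytest.approx(sigma_air ** 2, rel=0.05)


def test_lateral_sigma_matches_fermi_eyges_oracle(plain_library,
                                                  water_phantom,
                                                  spot_plan_150):
    """Fitted Gaussian width at mid-depth equals an independent numeric
    Fermi-Eyges quadrature within 2%."""
    cube = compute_dose_apb(spot_plan_150, water_phantom, 2.0,
                            idd_library=plain_library, secondary_halo=False)
    bl = spot_plan_150.beams[0].beamline
    z_mid = 101.0
    kz = int(np.argmin(np.abs(cube.axis_centers(2) - z_mid)))
    ic = cube.shape[0] // 2
    profile = cube.dose[:, ic, kz]
    x = cube.axis_centers(0)

    def gauss(x, a, s):
        return a * np.exp(-x ** 2 / (2 * s ** 2))

    (a, s_fit), _ = curve_fit(gauss, x, profile, p0=[profile.max(), 8.0])

    # independent oracle: direct quadrature of the Fermi-Eyges integral
    # sigma^2(z) = sigma_air^2 + int_0^z T(E(z')) (z - z')^2 dz'
    zq = np.linspace(0.0, z_mid, 4000)
    e_res = physics.energy_from_range(physics.range_from_energy(150.0) - zq)
    t = physics.scattering_power(np.clip(e_res, 3.0, None))
    sig2 = bl.spot_sigma_air(150.0) ** 2 + np.trapezoid(t * (z_mid - zq) ** 2,
                                                        zq)
    assert abs(s_fit) == pytest.approx(np.sqrt(sig2), rel=0.02)


def test_off_axis_heterogeneity_is_invisible(plain_library):
    """A bone insert 15 mm off the spot axis changes nothing: the slab
    approximation sees material along the central axis only."""
    water = build_slab_phantom([("water", 160.0)], lateral_size=80.0,
                               spacing=2.0)
    with_insert = build_slab_phantom([("water", 160.0)], lateral_size=80.0,
                                     spacing=2.0)
    # bone block at x in [15, 35] mm, i.e. never on the axis at x=0
    xc = with_insert.axis_centers(0)
    sel = (xc >= 15.0) & (xc <= 35.0)
    with_insert.material_index[sel, :, 20:40] = \
        with_insert.materials.index("bone")
    plan = single_spot_plan(150.0)
    d_water = compute_dose_apb(plan, water, 2.0, idd_library=plain_library)
    d_insert = compute_dose_apb(plan, with_insert, 2.0,
                                idd_library=plain_library)
    np.testing.assert_array_equal(d_water.dose, d_insert.dose)


def test_linearity_in_spot_weight(plain_library, water_phantom):
    d1 = compute_dose_apb(single_spot_plan(150.0, weight=1.0), water_phantom,
                          2.0, idd_library=plain_library)
    d3 = compute_dose_apb(single_spot_plan(150.0, weight=3.0), water_phantom,
                          2.0, idd_library=plain_library)
    np.testing.assert_allclose(d3.dose, 3.0 * d1.dose, rtol=1e-12, atol=1e-15)


def test_lateral_integral_equals_idd_without_attenuation(no_nuclear_library,
                                                         water_phantom):
    """With nuclear attenuation disabled the laterally integrated dose of a
    single spot reproduces the IDD (normalization conservation)."""
    plan = single_spot_plan(150.0)
    cube = compute_dose_apb(plan, water_phantom, 2.0,
                            idd_library=no_nuclear_library,
                            secondary_halo=False, n_sigma_window=6.0)
    bl = plan.beams[0].beamline
    curve = no_nuclear_library.curve(150.0)
    z = cube.axis_centers(2)
    pixel = cube.spacing[0] * cube.spacing[1]
    lat_int = cube.dose.sum(axis=(0, 1)) * pixel
    idd = curve(z) * bl.protons_per_mu / no_nuclear_library.protons_per_mu
    sel = idd > 0.02 * idd.max()
    np.testing.assert_allclose(lat_int[sel], idd[sel], rtol=2e-3)


def test_two_spot_symmetry(plain_library, water_phantom):
    """Equal-weight spots mirrored about x=0 give a field symmetric about
    their midplane to near machine precision."""
    from protonval.beamline import Beam, EnergyLayer, PBSPlan, Spot
    bl = BeamLineConfig(range_shifter_wet=0.0, air_gap=0.0)
    layer = EnergyLayer(150.0, [Spot(-7.0, 0.0, 150.0, 1.0),
                                Spot(7.0, 0.0, 150.0, 1.0)])
    plan = PBSPlan([Beam(np.array([0, 0, 1.0]), bl, [layer])])
    cube = compute_dose_apb(plan, water_phantom, 2.0,
                            idd_library=plain_library)
    flipped = cube.dose[::-1, :, :]
    denom = cube.dose.max()
    assert np.max(np.abs(cube.dose - flipped)) / denom < 1e-9


def test_oblique_beam_range_matches_en_face(plain_library):
    """A 30-degree beam through a water slab reaches the same radiological
    depth along its own axis as the en-face beam."""
    from protonval.beamline import Beam, EnergyLayer, PBSPlan, Spot
    ph = build_slab_phantom([("water", 180.0)], lateral_size=160.0,
                            spacing=2.0)
    bl = BeamLineConfig(range_shifter_wet=0.0, air_gap=0.0)
    ang = np.deg2rad(30.0)
    d = np.array([np.sin(ang), 0.0, np.cos(ang)])
    layer = EnergyLayer(120.0, [Spot(0.0, 0.0, 120.0, 1.0)])
    oblique = PBSPlan([Beam(d, bl, [layer])])
    cube = compute_dose_apb(oblique, ph, 2.0, idd_library=plain_library)
    # the Bragg peak must lie on the beam axis at the 120-MeV range
    idx = np.unravel_index(np.argmax(cube.dose), cube.shape)
    peak = np.array([cube.axis_centers(a)[idx[a]] for a in range(3)])
    slant = np.dot(peak, d)
    assert slant == pytest.approx(physics.range_from_energy(120.0), abs=4.0)


def test_degraded_plan_dose_bounded_by_parent(plain_library, water_phantom):
    """Nonnegative weights: removing spots can only lower the dose, voxel
    by voxel (exact for the deterministic engine)."""
    from protonval.beamline import Beam, BeamLineConfig, EnergyLayer, PBSPlan, Spot
    from protonval.planning import degrade_plan
    bl = BeamLineConfig(range_shifter_wet=0.0, air_gap=0.0)
    rng = np.random.default_rng(3)
    spots = [Spot(float(x), float(y), 150.0, float(rng.random() + 0.2))
             for x in (-10.0, 0.0, 10.0) for y in (-10.0, 0.0, 10.0)]
    plan = PBSPlan([Beam(np.array([0, 0, 1.0]), bl,
                         [EnergyLayer(150.0, spots)])])
    parent = compute_dose_apb(plan, water_phantom, 2.0,
                              idd_library=plain_library)
    child = compute_dose_apb(degrade_plan(plan, "spots", 0.4, seed=2),
                             water_phantom, 2.0, idd_library=plain_library)
    assert np.all(child.dose <= parent.dose + 1e-12)
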