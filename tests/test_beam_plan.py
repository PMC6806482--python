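"""Beamline model, IDD curves, SOBP optimization, plan construction and
degradation."""

import numpy as np
import pytest

from protonval import physics
from protonval.beamline import (Beam, BeamLineConfig, EnergyLayer, PBSPlan,
                                Spot, beam_frame)
from protonval.idd import bragg_idd, IDDLibrary
from protonval.phantom import build_slab_phantom
from protonval.planning import (create_uniform_plan, degrade_plan,
                                optimize_sobp,
                                override_heterogeneities_to_water)


class TestBeamLineConfig:
    def test_energies_must_increase(self):
        with pytest.raises(ValueError):
            BeamLineConfig(available_energies=(100.0, 90.0))

    def test_negative_geometry_rejected(self):
        with pytest.raises(ValueError):
            BeamLineConfig(range_shifter_wet=-1.0)

    def test_sigma_decreases_with_energy(self):
        bl = BeamLineConfig()
        assert bl.spot_sigma_air(200.0) < bl.spot_sigma_air(100.0)

    def test_range_shifter_pullback(self):
        bl = BeamLineConfig(range_shifter_wet=75.0)
        e_ph = bl.energy_at_phantom(150.0)
        r_after = physics.range_from_energy(e_ph)
        assert r_after == pytest.approx(physics.range_from_energy(150.0) - 75.0,
                                        abs=1e-9)

    def test_beam_frame_identity_for_en_face(self):
        e1, e2, d = beam_frame([0.0, 0.0, 1.0])
        np.testing.assert_allclose(e1, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(e2, [0, 1, 0], atol=1e-12)
        e1o, e2o, do = beam_frame([np.sin(0.5), 0.0, np.cos(0.5)])
        # right-handed orthonormal triad
        np.testing.assert_allclose(np.cross(e1o, e2o), do, atol=1e-12)


class TestBraggIDD:
    def test_distal_80_matches_power_law_range(self, idd_library):
        curve = bragg_idd(150.0, library=idd_library)
        # oracle: R = 0.0022 * 150^1.77 cm = 156 mm
        assert curve.distal_depth(0.8) == pytest.approx(156.0, abs=2.0)

    def test_nonnegative_and_unimodal(self, idd_library):
        for e in (90.0, 150.0, 210.0):
            c = bragg_idd(e, library=idd_library)
            d = c.dose_per_mu
            assert np.all(d >= 0)
            ipk = int(np.argmax(d))
            # the Bragg peak is the global maximum, well above the entrance
            assert d[ipk] > 2.0 * d[0]
            # monotone rise to the peak (outside the first two bins, where
            # the convolution boundary leaves a percent-level ripple) and
            # monotone fall beyond it
            rising = np.diff(d[2: ipk + 1])
            falling = np.diff(d[ipk:])
            # 1e-4 of max absorbs sub-permille ripple from the discrete
            # secondary-deposition kernel
            assert np.all(rising >= -1e-4 * d.max())
            assert np.all(falling <= 1e-4 * d.max())

    def test_range_shifter_shifts_distal_depth_by_its_wet(self, idd_library):
        free = idd_library.curve(150.0)
        shifted = idd_library.curve_for_beamline(
            150.0, BeamLineConfig(range_shifter_wet=75.0))
        shift = free.distal_depth(0.8) - shifted.distal_depth(0.8)
        assert shift == pytest.approx(75.0, abs=1.0)

    def test_out_of_range_energy_names_nearest(self):
        with pytest.raises(ValueError, match="230"):
            bragg_idd(260.0)

    def test_secondary_component_bounded_by_total(self, idd_library):
        c = idd_library.curve(180.0)
        sec = c.mev_per_mm_secondary
        assert sec is not None
        assert np.all(sec <= c.mev_per_mm + 1e-12)
        assert np.all(sec >= 0)


class TestSOBP:
    def test_reference_beam_flat_and_on_range(self, idd_library):
        res = optimize_sobp(idd_library=idd_library)
        assert res.plateau_flatness <= 0.01
        assert res.distal_90_mm == pytest.approx(250.0, abs=1.0)

    def test_single_layer_degenerates_to_pristine_peak(self, idd_library):
        res = optimize_sobp(target_range_mm=250.0, modulation_mm=0.0,
                            idd_library=idd_library)
        energies = {l.energy for b in res.plan.beams for l in b.layers}
        assert len(energies) == 1
        assert np.isnan(res.plateau_flatness)

    def test_flatness_degrades_with_coarser_layers(self, idd_library):
        fine = optimize_sobp(layer_range_step_mm=3.0, idd_library=idd_library)
        coarse = optimize_sobp(layer_range_step_mm=5.0, idd_library=idd_library)
        assert coarse.plateau_flatness >= fine.plateau_flatness

    def test_too_few_layers_reports_achievable_flatness(self, idd_library):
        with pytest.raises(ValueError, match="flatness"):
            optimize_sobp(layer_range_step_mm=12.0, idd_library=idd_library)

    def test_modulation_larger_than_range_rejected(self, idd_library):
        with pytest.raises(ValueError):
            optimize_sobp(target_range_mm=100.0, modulation_mm=150.0,
                          idd_library=idd_library)


class TestPlanJSON:
    def test_round_trip(self, tmp_path):
        bl = BeamLineConfig()
        layers = [EnergyLayer(150.0, [Spot(1.0, -2.0, 150.0, 0.5),
                                      Spot(3.0, 4.0, 150.0, 1.5)]),
                  EnergyLayer(160.0, [Spot(0.0, 0.0, 160.0, 2.0)])]
        plan = PBSPlan([Beam(np.array([0.0, 0.0, 1.0]), bl, layers, "b1")],
                       "test-plan")
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = PBSPlan.from_json(path)
        assert back.label == plan.label
        assert back.n_spots == plan.n_spots
        assert back.total_mu == pytest.approx(plan.total_mu)
        s0 = back.beams[0].layers[0].spots[0]
        assert (s0.x, s0.y, s0.weight) == (1.0, -2.0, 0.5)
        # round-trip is stable: serializing again gives identical text
        assert back.to_json() == plan.to_json()

    def test_empty_layer_rejected(self):
        bl = BeamLineConfig()
        with pytest.raises(ValueError):
            Beam(np.array([0, 0, 1.0]), bl, [EnergyLayer(150.0, [])])


class TestDegradePlan:
    def _plan(self, n_spots=100, n_layers=10):
        bl = BeamLineConfig()
        rng = np.random.default_rng(0)
        layers = []
        per = n_spots // n_layers
        for i in range(n_layers):
            e = 100.0 + i
            layers.append(EnergyLayer(e, [
                Spot(float(x), 0.0, e, float(rng.random() + 0.1))
                for x in range(per)]))
        return PBSPlan([Beam(np.array([0, 0, 1.0]), bl, layers)], "p")

    def test_fraction_zero_is_identity(self):
        plan = self._plan()
        out = degrade_plan(plan, "spots", 0.0, seed=1)
        assert out.n_spots == plan.n_spots
        assert sorted((s.x, s.energy, s.weight) for b in out.beams
                      for l in b.layers for s in l.spots) == \
               sorted((s.x, s.energy, s.weight) for b in plan.beams
                      for l in b.layers for s in l.spots)

    def test_spot_removal_count_and_determinism(self):
        plan = self._plan(100)
        out1 = degrade_plan(plan, "spots", 0.3, seed=42)
        out2 = degrade_plan(plan, "spots", 0.3, seed=42)
        assert out1.n_spots == 70
        assert out1.to_json() == out2.to_json()
        assert degrade_plan(plan, "spots", 0.3, seed=43).to_json() \
            != out1.to_json()
        # original untouched
        assert plan.n_spots == 100

    def test_layer_removal_keeps_layers_intact(self):
        plan = self._plan(96, 8)  # 12 spots in each of 8 layers
        out = degrade_plan(plan, "layers", 0.5, seed=5)
        layers = [l for b in out.beams for l in b.layers]
        assert len(layers) == 4
        for l in layers:
            assert len(l.spots) == 12

    def test_full_removal_rejected(self):
        plan = self._plan(10, 2)
        with pytest.raises(ValueError):
            degrade_plan(plan, "spots", 0.99999, seed=1)
        with pytest.raises(ValueError):
            degrade_plan(plan, "layers", 0.75, seed=1)  # would leave 0 of 2


class TestUniformPlan:
    def test_override_noop_in_water(self, idd_library):
        ph = build_slab_phantom([("water", 120.0)], lateral_size=80.0,
                                spacing=2.0)
        box = ((-15.0, 15.0), (-15.0, 15.0), (60.0, 75.0))
        bl = BeamLineConfig(range_shifter_wet=0.0, air_gap=0.0)
        kw = dict(beamline=bl, idd_library=idd_library,
                  spot_pitch_factor=1.0)
        p_on = create_uniform_plan(ph, box, override_to_water=True, **kw)
        p_off = create_uniform_plan(ph, box, override_to_water=False, **kw)
        assert p_on.to_json() == p_off.to_json()

    def test_box_outside_phantom_rejected(self, idd_library):
        ph = build_slab_phantom([("water", 50.0)], 40.0, 2.0)
        with pytest.raises(ValueError):
            create_uniform_plan(ph, ((-10, 10), (-10, 10), (40.0, 80.0)),
                                idd_library=idd_library)

    def test_spot_lattice_covers_target_with_margin(self, idd_library):
        """A 1 x 5 x 7 cm^3 box gets a spot lattice spanning at least
        50 x 70 mm laterally."""
        from protonval.phantom import NeckAnalogConfig, build_neck_analog
        from protonval.pipeline import (ExperimentConfig, PlanSpec,
                                        build_study_phantom,
                                        build_study_plans)
        cfg = ExperimentConfig(plans=(PlanSpec("F1", stacks_mm=(2.0,)),))
        ph, surf = build_study_phantom(cfg)
        plan = build_study_plans(cfg, ph, surf, idd_library)["F1"]
        xs = [s.x for b in plan.beams for l in b.layers for s in l.spots]
        ys = [s.y for b in plan.beams for l in b.layers for s in l.spots]
        assert max(xs) - min(xs) >= 70.0
        assert max(ys) - min(ys) >= 50.0

    def test_override_fills_enclosed_air_and_bone(self):
        from protonval.phantom import NeckAnalogConfig, build_neck_analog
        ph = build_neck_analog(NeckAnalogConfig(spacing=2.0))
        over = override_heterogeneities_to_water(ph)
        names = over.materials.names
        counts = over.material_name_grid_counts()
        assert counts["bone"] == 0
        assert counts["soft_tissue"] == 0
        # external air preserved, internal channel filled
        assert counts["air"] < ph.material_name_grid_counts()["air"]
        assert counts["air"] > 0
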