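"""End-to-end synthetic validation studies.

``run_validation`` reproduces, on synthetic phantoms, the workflow of a
planar-array dose-validation campaign:

1. build the phantom (neck analog with a bone/air heterogeneity, or the
   water-breast analog) plus its water-override copy;
2. construct deliberately nonuniform plans: optimize a uniform dose to a
   target box on the override phantom, then recalculate on the true phantom
   (plans F1/F3), and degrade copies by removing random spots or whole
   energy layers (F2/F4);
3. compute APB and Monte Carlo dose cubes for every plan;
4. generate virtual detector measurements at the configured depths from a
   separate, higher-statistics Monte Carlo run with channel noise — the
   stand-in for physical measurements, which do not exist for synthetic
   phantoms (pass rates therefore probe the pipeline's sensitivity, not any
   physical measurement);
5. run 2D gamma with depth-of-best-agreement search and sparse-reference 3D
   gamma for both engines at 2%/2mm, 3%/3mm and 5%/3mm;
6. emit a table-style report (CSV + Markdown) with per-engine averages.

Everything is deterministic under the configured seeds, including the Monte
Carlo runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import zlib

import numpy as np
import pandas as pd
import yaml

from . import mc
from .apb import compute_dose_apb
from .beamline import BeamLineConfig, PBSPlan
from .detector import simulate_measurement, write_opg, measurement_geometry
from .dose import DoseCube
from .gamma import (STANDARD_CRITERIA, GammaCriterion, depth_search, gamma_2d,
                    gamma_3d, extract_plane, resample_plane,
                    SEARCH_RADIUS_FACTOR)
from .idd import IDDLibrary
from .phantom import (BreastAnalogConfig, NeckAnalogConfig, build_breast_analog,
                      build_neck_analog, neck_cut_plane_z)
from .planning import create_uniform_plan, degrade_plan

logger = logging.getLogger(__name__)


@dataclass
class PlanSpec:
    """One plan of the study: either freshly optimized or a degraded copy."""

    name: str
    #: stack thicknesses (mm of solid water) between phantom and detector
    stacks_mm: tuple = (2.0, 19.4)
    #: lateral shift (mm) of the target box, to vary the dose pattern
    box_shift_x: float = 0.0
    #: proximal face of the target box below the cut (None = config default)
    box_depth_mm: float | None = None
    #: gantry angle (degrees about the y axis; 0 = en face along +z)
    gantry_angle_deg: float = 0.0
    #: degrade the named parent instead of optimizing ("" = optimize)
    degrade_parent: str = ""
    degrade_mode: str = "spots"
    degrade_fraction: float = 0.3
    degrade_seed: int = 101


@dataclass
class ExperimentConfig:
    phantom_kind: str = "neck"                   # "neck" | "breast"
    neck: NeckAnalogConfig = field(default_factory=NeckAnalogConfig)
    breast: BreastAnalogConfig = field(default_factory=BreastAnalogConfig)
    beamline: BeamLineConfig = field(default_factory=BeamLineConfig)
    #: target box size (x, y, z) mm; the study uses 10 x 50 x 70 mm^3 boxes
    #: (depth x height x width) drawn in the downstream solid water
    target_box_size: tuple = (70.0, 50.0, 10.0)
    target_box_depth_mm: float = 20.0            # proximal face below the cut
    prescription_gy: float = 2.0
    plans: tuple = (
        PlanSpec("F1", stacks_mm=(2.0, 19.4)),
        PlanSpec("F2", stacks_mm=(2.0, 19.4), degrade_parent="F1",
                 degrade_mode="spots", degrade_fraction=0.3, degrade_seed=101),
        PlanSpec("F3", stacks_mm=(2.0, 28.2), box_shift_x=8.0,
                 box_depth_mm=22.0),
        PlanSpec("F4", stacks_mm=(2.0, 19.4), degrade_parent="F3",
                 degrade_mode="layers", degrade_fraction=0.4, degrade_seed=202),
    )
    grid_spacing: float = 2.0                    # dose grid (mm)
    mc_seed: int = 20_000
    mc_uncertainty_eval: float = 0.020
    mc_uncertainty_meas: float = 0.016
    mc_batch_histories: int = 500_000
    mc_max_histories: int = 40_000_000
    noise_sigma: float = 0.01
    calibration_factor: float = 1.0
    criteria: tuple = STANDARD_CRITERIA
    threshold_2d: float = 5.0
    threshold_3d: float = 10.0
    depth_search_criterion: GammaCriterion = field(
        default_factory=lambda: GammaCriterion(2.0, 2.0))
    depth_window_mm: float = 5.0
    depth_step_mm: float = 0.1
    out_dir: str | None = None

    # ---- YAML -------------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return _config_from_dict(d)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _config_from_dict(d: dict) -> "ExperimentConfig":
    kw = dict(d)
    if "neck" in kw:
        neck = dict(kw["neck"])
        for key in ("complex_offset", "lateral_size"):
            if key in neck:
                neck[key] = tuple(neck[key])
        kw["neck"] = NeckAnalogConfig(**neck)
    if "breast" in kw:
        br = dict(kw["breast"])
        if "lateral_size" in br:
            br["lateral_size"] = tuple(br["lateral_size"])
        kw["breast"] = BreastAnalogConfig(**br)
    if "beamline" in kw:
        bl = dict(kw["beamline"])
        if "available_energies" in bl:
            bl["available_energies"] = tuple(bl["available_energies"])
        kw["beamline"] = BeamLineConfig(**bl)
    if "plans" in kw:
        kw["plans"] = tuple(PlanSpec(**{**p, "stacks_mm": tuple(p["stacks_mm"])})
                            for p in kw["plans"])
    if "criteria" in kw:
        kw["criteria"] = tuple(GammaCriterion(**c) for c in kw["criteria"])
    if "depth_search_criterion" in kw:
        kw["depth_search_criterion"] = GammaCriterion(
            **kw["depth_search_criterion"])
    for key in ("target_box_size",):
        if key in kw:
            kw[key] = tuple(kw[key])
    return ExperimentConfig(**kw)


@dataclass
class ValidationReport:
    rows: pd.DataFrame
    engine_averages: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.4f")

    def to_markdown(self, path=None) -> str:
        lines = ["# Validation report", "", self.rows.to_markdown(index=False,
                                                                  floatfmt=".2f"),
                 "", "## Per-engine averages", "",
                 self.engine_averages.to_markdown(index=False, floatfmt=".2f"), ""]
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_study_phantom(config: ExperimentConfig):
    """(true phantom, surface z of the measurement stack)."""
    if config.phantom_kind == "neck":
        ph = build_neck_analog(config.neck)
        return ph, neck_cut_plane_z(config.neck)
    if config.phantom_kind == "breast":
        ph = build_breast_analog(config.breast)
        return ph, config.breast.upstream_air + config.breast.dome_radius
    raise ValueError(f"unknown phantom kind {config.phantom_kind!r}")


def build_study_plans(config: ExperimentConfig, phantom, surface_z: float,
                      idd_library: IDDLibrary) -> dict[str, PBSPlan]:
    """Optimized plans (F1/F3-style, or en-face/oblique for the breast
    analog) and their degraded copies.

    Neck plans target a box in the downstream solid water; breast plans
    target an irregular volume crossing from the water dome into the slab
    (the box is clipped to non-air voxels during optimization).
    """
    plans: dict[str, PBSPlan] = {}
    sx, sy, sz = config.target_box_size
    for spec in config.plans:
        if spec.degrade_parent:
            continue
        if config.phantom_kind == "breast":
            # irregular target across the dome/slab interface
            box = ((spec.box_shift_x - sx / 2.0, spec.box_shift_x + sx / 2.0),
                   (-sy / 2.0, sy / 2.0),
                   (surface_z - 20.0, surface_z + 10.0))
        else:
            depth = spec.box_depth_mm if spec.box_depth_mm is not None \
                else config.target_box_depth_mm
            z0 = surface_z + depth
            box = ((spec.box_shift_x - sx / 2.0, spec.box_shift_x + sx / 2.0),
                   (-sy / 2.0, sy / 2.0), (z0, z0 + sz))
        ang = np.deg2rad(spec.gantry_angle_deg)
        direction = (np.sin(ang), 0.0, np.cos(ang))
        plans[spec.name] = create_uniform_plan(
            phantom, box, beam_direction=direction,
            beamline=config.beamline, override_to_water=True,
            prescription_gy=config.prescription_gy,
            idd_library=idd_library, label=spec.name)
    for spec in config.plans:
        if spec.degrade_parent:
            plans[spec.name] = degrade_plan(plans[spec.degrade_parent],
                                            spec.degrade_mode,
                                            spec.degrade_fraction,
                                            spec.degrade_seed)
            plans[spec.name].label = spec.name
    return plans


def compare_engines(apb_cube: DoseCube, mc_cube: DoseCube,
                    region_z: tuple[float, float] | None = None,
                    threshold_fraction: float = 0.10) -> dict:
    """Voxelwise APB-vs-MC discrepancy summary, normalized to the MC maximum.

    ``region_z`` restricts the summary to a z-interval (mm, cube frame),
    e.g. the solid-water region distal to a bone/air interface.  Voxels
    below ``threshold_fraction`` of the MC maximum (in both cubes) are
    ignored.  Returns max and 95th-percentile |dD| / max(D_MC) in percent.
    """
    if apb_cube.shape != mc_cube.shape or \
            not np.allclose(apb_cube.spacing, mc_cube.spacing):
        raise ValueError("cubes must share one grid")
    norm = mc_cube.max_dose()
    diff = np.abs(apb_cube.dose - mc_cube.dose) / norm
    mask = (mc_cube.dose > threshold_fraction * norm) | \
           (apb_cube.dose > threshold_fraction * norm)
    if region_z is not None:
        zc = mc_cube.axis_centers(2)
        zmask = (zc >= region_z[0]) & (zc <= region_z[1])
        mask &= zmask[None, None, :]
    if not np.any(mask):
        raise ValueError("empty comparison region")
    vals = diff[mask]
    return {"max_percent": float(100.0 * vals.max()),
            "p95_percent": float(100.0 * np.percentile(vals, 95.0)),
            "n_voxels": int(vals.size)}


def run_validation(config: ExperimentConfig,
                   idd_library: IDDLibrary | None = None) -> ValidationReport:
    """Execute the full study; see the module docstring for the stages."""
    lib = idd_library if idd_library is not None else IDDLibrary()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("[stage:%s]", name)

    stage("phantom")
    phantom, surface_z = build_study_phantom(config)
    stage("plans")
    plans = build_study_plans(config, phantom, surface_z, lib)

    rows = []
    specs = {s.name: s for s in config.plans}
    for pname, plan in plans.items():
        spec = specs[pname]
        stage(f"dose:{pname}")
        apb_cube = compute_dose_apb(plan, phantom, config.grid_spacing,
                                    idd_library=lib)
        mc_cube, mc_stats = mc.transport(
            plan, phantom, config.grid_spacing,
            uncertainty_target=config.mc_uncertainty_eval,
            seed=config.mc_seed + zlib.crc32(pname.encode()) % 1000,
            batch_histories=config.mc_batch_histories,
            max_histories=config.mc_max_histories, idd_library=lib)
        meas_cube, meas_stats = mc.transport(
            plan, phantom, config.grid_spacing,
            uncertainty_target=config.mc_uncertainty_meas,
            seed=config.mc_seed + 5000 + zlib.crc32(pname.encode()) % 1000,
            batch_histories=config.mc_batch_histories,
            max_histories=config.mc_max_histories, idd_library=lib)
        if out is not None:
            apb_cube.save(out / f"{pname}_apb.npz")
            mc_cube.save(out / f"{pname}_mc.npz")
            (out / f"{pname}_mc_runstats.json").write_text(mc_stats.to_json())
            plan.to_json(out / f"{pname}_plan.json")

        for stack in spec.stacks_mm:
            stage(f"measure:{pname}@{stack}mm")
            meas = simulate_measurement(
                meas_cube, stack, surface_z,
                noise_sigma=config.noise_sigma,
                calibration_factor=config.calibration_factor,
                seed=config.mc_seed + 9000 + int(10 * stack)
                + zlib.crc32(pname.encode()) % 997)
            d_m, geometric = measurement_geometry(stack)
            cube_front = meas_cube.origin[2] - meas_cube.spacing[2] / 2.0
            d_e = surface_z + geometric - cube_front
            if out is not None:
                write_opg(meas, out / f"{pname}_dm{d_m:.0f}.opg")

            ref_vals, ref_origin, ref_sp = resample_plane(
                meas.values, meas.origin, meas.pitch, target_spacing=2.0)
            x_det, y_det = meas.channel_positions()
            xx, yy = np.meshgrid(x_det, y_det, indexing="ij")
            zplane = surface_z + geometric
            pts3 = np.stack([xx.ravel(), yy.ravel(),
                             np.full(xx.size, zplane)], axis=1)

            for engine, cube in (("APB", apb_cube), ("MC", mc_cube)):
                stage(f"gamma:{pname}:{engine}@{d_m:.0f}mm")
                row = {"engine": engine, "plan": pname, "d_m": round(d_m, 2),
                       "d_e": round(d_e, 2)}
                margin = SEARCH_RADIUS_FACTOR * 3.0 + ref_sp
                ex = np.arange(ref_origin[0] - margin,
                               ref_origin[0] + (ref_vals.shape[0] - 1) * ref_sp
                               + margin + 1e-9, ref_sp)
                ey = np.arange(ref_origin[1] - margin,
                               ref_origin[1] + (ref_vals.shape[1] - 1) * ref_sp
                               + margin + 1e-9, ref_sp)
                eval_plane = extract_plane(cube, d_e, ex, ey)
                for crit in config.criteria:
                    c2 = GammaCriterion(crit.dose_percent, crit.dta_mm,
                                        config.threshold_2d)
                    res = gamma_2d(ref_vals, ref_origin, ref_sp, eval_plane,
                                   (ex[0], ey[0]), ref_sp, c2)
                    row[f"2D {c2.label}"] = round(res.pass_rate, 2)
                ds_crit = GammaCriterion(config.depth_search_criterion.dose_percent,
                                         config.depth_search_criterion.dta_mm,
                                         config.threshold_2d)
                ds = depth_search(ref_vals, ref_origin, ref_sp, cube,
                                  d_e=d_e, d_m=d_m, criterion=ds_crit,
                                  window_mm=config.depth_window_mm,
                                  step_mm=config.depth_step_mm)
                row["d_gamma"] = round(ds.d_gamma, 2)
                row["d_e-d_gamma"] = round(ds.delta, 2)
                for crit in config.criteria:
                    c3 = GammaCriterion(crit.dose_percent, crit.dta_mm,
                                        config.threshold_3d)
                    try:
                        res3 = gamma_3d(pts3, meas.values.ravel(), cube, c3)
                        row[f"3D {c3.label}"] = round(res3.pass_rate, 2)
                    except ValueError:
                        logger.warning("3D gamma empty for %s %s d_m=%.1f",
                                       engine, pname, d_m)
                        row[f"3D {c3.label}"] = float("nan")
                rows.append(row)

    df = pd.DataFrame(rows)
    col_order = (["engine", "plan", "d_m", "d_e", "d_gamma", "d_e-d_gamma"]
                 + [c for c in df.columns if c.startswith("2D ")]
                 + [c for c in df.columns if c.startswith("3D ")])
    df = df[col_order]
    num_cols = [c for c in df.columns if c.startswith(("2D ", "3D "))] \
        + ["d_e-d_gamma"]
    avg = df.groupby("engine", sort=False)[num_cols].mean().reset_index()
    report = ValidationReport(rows=df, engine_averages=avg)
    if out is not None:
        report.to_csv(out / "report.csv")
        report.to_markdown(out / "report.md")
    return report
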