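# Methods

`protonval` is a desk-scale computational testbench for proton
pencil-beam-scanning (PBS) dose calculation. It pairs two dose engines — an
analytical pencil beam (APB) built on the infinite-slab approximation and a
condensed-history Class II Monte Carlo (MC) — with synthetic heterogeneous
phantoms, a virtual planar ionization-chamber array, and 2D/3D global
gamma-index analysis including a depth-of-best-agreement search. The point
of the package is to reproduce, under fully controlled synthetic conditions,
the *methodology* of a planar-array dose-validation campaign: where the two
engines agree, where the slab approximation breaks down at discrete
bone/air interfaces, and how well the gamma machinery localizes the depth
of best agreement.

## Shared transport physics

Both engines consume one parameterized physics layer (`protonval.physics`):

* **Range–energy**: the Bragg–Kleeman power law `R = alpha E^p` with
  `alpha = 0.0022 cm MeV^-p`, `p = 1.77` (R in water). Stopping power is its
  derivative, `S(E) = E^(1-p) / (alpha p)`, a standard parameterized
  stand-in for the Bethe–Bloch formula; at 150 MeV this gives 5.42 MeV/cm
  and a range of 156 mm.
* **Multiple Coulomb scattering**: Gaussian small-angle theory with the
  Highland width. The Highland logarithmic correction is *frozen at a
  reference thickness of 1 cm of water*, which makes the per-step angular
  variance strictly additive under step subdivision — a requirement for a
  condensed-history code and for consistency with the Fermi–Eyges integral
  the APB uses. The price is a few-percent error in the width for steps far
  from 1 cm; since both engines share the same scattering power, the error
  cancels in cross-engine comparisons.
* **Energy-loss straggling**: Bohr's Gaussian model with variance
  `0.0087 MeV^2 per mm` of water-equivalent path. Propagated to depth this
  gives a range-straggling sigma of ~1.0% of range at 150 MeV.
* **Nonelastic nuclear interactions** (`NuclearModel`): a piecewise-linear
  macroscopic cross section in water anchored at ~1.2%/cm above 100 MeV with
  an 8-MeV threshold, and a fixed energy partition per interaction:
  secondary proton 0.55, deuteron 0.05, alpha 0.05, neutrals 0.25 (removed
  from the simulation), heavy recoils 0.10 (local). Secondary protons are
  emitted with an `exp(kappa cos theta)` forward-peaked distribution
  (`kappa = 2`). These replace tabulated nuclear data libraries with a
  small, explicit, config-overridable model; magnitudes are set to typical
  published water values, not fitted to anything downstream.

Materials are summarized by mass density, relative stopping power (RSP),
radiation length, mean ionization energy, and a multiplier on water's
nonelastic cross section. Water has RSP 1 exactly; the solid-water slab
material has RSP 1.03; bone defaults to 1.85 g/cm^3 with RSP 1.60 (typical
cortical values). A 3-anchor piecewise-linear HU calibration (air / water /
bone) is provided for voxel-volume import.

## Integrated depth dose and the beamline

Pristine-peak IDD curves are built by 1D numerical transport with the same
physics: CSDA slowing-down, depth-dependent Bohr straggling (each source
depth smeared with the straggle accumulated *up to that depth*, so the
entrance stays sharp and the peak gets the full range straggling), primary
fluence attenuation, local deposition of the heavy/fragment shares, and a
secondary-proton deposition kernel obtained by projecting a recursive
straight-path profile over the emission-angle distribution. The curve keeps
its secondary-proton component separately; the APB deposits that component
with a wide halo Gaussian (15 mm default) so the lateral allocation of
secondary energy matches the MC's behaviour — the description of the APB
lateral fluence includes nonelastic nuclear scattering, and without this
term the engines disagree by 5–9% in-field even in water, masking the slab
artifacts the package exists to expose.

The range shifter is pure upstream water-equivalent thickness: both engines
pull the energy back by the shifter WET, add the corresponding Bohr energy
spread, and scale by the primary survival probability through the shifter
(secondaries created in the shifter are dropped by both engines alike).
Spot size in air is `sigma(E) = 12 - 0.035 (E - 70) mm` plus 0.05 mm per mm
of air gap — representative nozzle values, configurable, not machine data.

## APB engine

Per spot: water-equivalent depth (WED) is accumulated by exact voxel
raytracing **along the spot's central axis only**; the dose is
`weight x IDD(WED(z)) x Gaussian(sigma(z))` with
`sigma^2(z) = sigma_air^2 + sigma_MCS^2(z)`, the latter a Fermi–Eyges
accumulation of the Highland scattering power (with local material radiation
length) using geometric lever arms. Material off the axis is invisible —
the defining slab limitation, verified bit-exactly by test. Optional N x N
"mini-beam" sub-pencil splitting refines the lateral WED sampling. Oblique
beams are computed on a beam-aligned nearest-neighbour resampling of the
phantom and trilinearly mapped back (grid-spacing-level smoothing).

## MC engine

Histories are sampled per spot proportional to weight, started from the
spot Gaussian at the phantom face and transported with macro-steps of up to
three voxel crossings within one material (scattering and straggling
variances are additive, so grouping changes no moments); steps are also
capped by an 8% fractional energy loss (midpoint rule) and a voxel
diagonal. Nuclear interactions are placed by exponential optical depth;
deuterons/alphas deposit along straight-line CSDA tracks with
species-scaled ranges; delta electrons are absorbed locally; transport cuts
off at 1 MeV with local deposition. An exact energy ledger
(deposited + escaped = injected) closes to machine precision and is asserted
to 0.1% in tests.

Statistical uncertainty uses the batch method (default batches of 5x10^5
histories); the default stopping rule halts when the mean relative standard
error over voxels above half the maximum dose falls below 0.5%. Per-voxel
relative uncertainty is stored alongside the dose cube.

**Variance reduction.** For laterally homogeneous phantoms and en-face
beams, `lateral_replay=K` records each history's energy deposits relative
to its entry point and replays them at K fresh lateral samples of the same
spot Gaussian with weight 1/K (track repeating). In water the physics of a
track is independent of its lateral entry point, so the estimator is
unbiased, and batches remain iid so the batch uncertainty estimate is
valid. This is used for the water-phantom stopping-rule study; heterogeneous
phantoms always use analog sampling. The RNG is a xoroshiro128+ stream with
cached Box–Muller Gaussians, seeded per batch from one master seed, so runs
are bit-reproducible.

Both engines compute on the same nearest-neighbour-resampled material grid
(the dose grid), so material-boundary voxelization is identical between
them and cross-engine differences isolate the transport approximations.

## Plans

* `optimize_sobp` builds the calibration-style beam: layer weights by
  nonnegative least squares against a flat 2-Gy plateau, with the deepest
  layer iterated so the distal 90% dose point lands on the requested range.
  The default reference configuration (25-cm range, 10-cm modulation)
  reaches ~0.8% plateau flatness and hits the range within 1 mm.
* `create_uniform_plan` places a spot lattice (0.85 sigma pitch) over a
  target box, selects energy layers from the box's WED span, and solves a
  Tikhonov-regularized NNLS on sample points inside the box (air points
  excluded, so irregular targets crossing curved surfaces work). The ridge
  term spreads weight over neighbouring spots instead of the sparse spikes
  plain NNLS returns. Optimization runs on a copy of the phantom whose
  internal heterogeneities are overridden to water (enclosed air cavities
  found by connected components, treating the extruded anatomy axis as
  closed); recalculating the returned plan on the true phantom yields the
  deliberately nonuniform distributions used for engine stress-testing.
* `degrade_plan` removes `ceil(fraction x N)` random spots or whole energy
  layers under a fixed seed.

## Detector and OPG ASCII

The virtual array is a 7-mm-pitch lattice of point-sampling channels with
6 mm water-equivalent buildup; placing it under `t` mm of solid water gives
a measurement depth `d_m = 1.03 t + 6` mm below the surface. Channels apply
a cross-calibration factor and independent 1% Gaussian noise (both
configurable); an optional 4-mm averaging kernel emulates chamber size (off
by default). Planes persist as a small self-describing ASCII dialect
(tagged header + row-major matrix) documented in `detector.write_opg`,
round-trip stable to 1e-6 Gy and tolerant of CRLF endings.

## Gamma analysis

Global, absolute-dose gamma: dose differences are normalized to the maximum
of the computed (evaluation) distribution, reference points below a
threshold (5% in 2D, 10% in 3D) are excluded, and no rescaling of either
distribution is applied. In 2D the measured plane — first interpolated from
the 7-mm pitch to a 2-mm grid — is the reference against a computed plane
extracted from the cube (bilinear in-plane, linear in depth); in 3D the
sparse measured points are the reference against the full cube. The
evaluation is linearly interpolated onto a subgrid of about DTA/10 (rounded
to divide the evaluation spacing exactly, so identical distributions give
gamma = 0 identically) and searched within 3 x DTA, scanning candidates in
order of increasing distance with early exit — which is *exactly* equal to
brute force over the same subgrid, as the tests verify to 1e-9.

The depth-of-best-agreement search extracts evaluation planes over
`d_e ± 5 mm` in 0.1-mm steps and picks the depth maximizing the pass rate
at the analysis criterion (2%/2mm by default), tie-broken by minimal mean
gamma, then by depth closest to `d_e`; the normalization is the evaluation
plane at `d_e`, held fixed so the trace is comparable across depths.

## Synthetic phantoms and what they do (not) represent

* **Slab stacks**: water/solid-water/bone layers, used for oracles.
* **Neck analog**: an elliptical soft-tissue cylinder (70 x 32 mm
  semi-axes — wider than tall, as anatomy is) holding a bone annulus
  (6–10 mm radii, RSP 1.60) around a 4.5-mm-radius air channel, offset
  anteriorly; the cylinder is cut flat 8 mm past its axis and rests on
  45 mm of solid water where the measurement planes live. The bone/air
  sizes are tuned so a single anterior beam produces the discrete-interface
  regime in which slab engines fail (APB-vs-MC differences of tens of
  percent distal to the interface) while the *overall* lateral
  heterogeneity stays limited, as it was for the real animal phantoms.
* **Breast analog**: a 45-mm water hemisphere on 40 mm of solid water, with
  en-face and 30-degree oblique beams and an irregular target crossing into
  the slab.

The virtual "measurement" is a separate, higher-statistics MC run sampled
by the detector model with 1% channel noise. This stand-in defines what the
validation studies can and cannot show: pass rates and depth-agreement
numbers probe the *pipeline's sensitivity and the inter-engine physics*,
not agreement with any physical measurement — real detector response
(volume averaging, LET dependence, positioning error) and real anatomy are
outside the model.

## Study configuration

The neck study builds four plans: F1 and F3 are optimized on the
water-override phantom to deliver 2 Gy to 1 x 5 x 7 cm^3 boxes in the
downstream solid water (F3 shifted laterally and deeper), then recalculated
on the true phantom; F2 removes 30% of F1's spots and F4 removes 40% of
F3's energy layers, at fixed seeds. Boxes start 20 mm (F1/F2) and 22 mm
(F3/F4) below the cut so that the 8-mm measurement plane is proximal to the
SOBP, the 26-mm planes lie inside it, and only F3's 35-mm plane sits in the
distal falloff — matching where the study's analysis depths fell relative
to its dose distributions. Reports list, per engine/plan/depth: `d_m`,
`d_e`, `d_gamma`, their difference, and 2D/3D pass rates at 2%/2mm, 3%/3mm
and 5%/3mm, plus per-engine averages (CSV + Markdown).

## Problem sizes and numerical choices

Chosen once for desk-scale single-core execution and used consistently:

* dose grids 2 mm (phantoms are built at 1 mm and resampled);
* the water-phantom stopping-rule run keeps the full reference-beam depth
  structure but a 4 x 4 cm lateral field, with 16-fold lateral replay;
* neck-study MC: ~2% relative uncertainty for evaluated cubes and ~1.8–2%
  for the measurement-source cubes (the measurement is fixed across a depth
  search, so its noise does not jitter the trace);
* IDD depth bin 0.5 mm; secondary-proton kernels on a 28-point geometric
  energy grid with linear interpolation between bracketing kernels;
* depth search window ±5 mm, step 0.1 mm;
* NNLS ridge weight `0.02 x mean column norm`; optimizer sample spacing
  4 mm; spot lattice margin 7 mm; layer spacing 2.5–3 mm of range.

## Known limitations

* The beamline (spot sizes, energies, MU calibration) is representative,
  not a machine model; absolute MU values are internally consistent only.
* Goudsmit–Saunderson is reduced to its Gaussian core: no single-scatter
  tails, so out-of-field halo beyond a few sigma is underestimated by both
  engines.
* The nuclear model's fixed energy partition and single-parameter
  anisotropy are caricatures of double-differential emission data; they are
  identical in both engines and in the IDD, so cross-engine comparisons are
  insensitive to them to first order.
* The APB halo is a single Gaussian of fixed width; the true secondary
  spread grows with depth.
* Secondary protons of secondaries beyond the second generation deposit
  locally in the IDD builder (sub-percent effect).
* Oblique APB fields inherit grid-spacing-level smoothing from the
  resample-and-rotate implementation.
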