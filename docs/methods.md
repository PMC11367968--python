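# Methods

## Problem setting

An extrinsic stenosis of an HM3 outflow graft is a localized external
compression of a compliant but effectively rigid ~17 mm conduit carrying the
device output (3.5–5.5 L/min of blood) into the aorta. The clinically
reported severity measure is the narrowest lumen cross-sectional area (CSA).
`graftflow` quantifies, per (severity, flow) condition, the pressure
gradient over the stenotic segment, the peak velocity, and the volume-
integrated turbulent kinetic energy (TKE), and correlates these against
severity and device flow.

## Geometry model

The graft is a straight tube of uniform baseline radius `R₀` with an inward
wall-displacement bump

    c(s) = A · cos²(π (s − s₀) / L)   for |s − s₀| < L/2,  else 0,

where `s` is the axial coordinate from the graft inlet, `s₀` the stenosis
centre and `L` its extent. The cosine-squared form is continuously
differentiable at the bump edges; smoothness avoids spurious pressure
spikes at the stenosis shoulders. Compression may be concentric or applied
from one side: the azimuthal displacement weight is
`(1 − e) + e·(1 + cos θ)` for eccentricity `e ∈ [0, 1]`, so `e = 1` models
material accumulating on one wall (between graft and bend relief) and
`e = 0` the concentric equivalent. Severity is always specified by the
narrowest CSA; the amplitude `A` is solved analytically (concentric) or by
bracketing root search on the azimuthal-quadrature area (eccentric).
"Virtual augmentation" multiplies `c(s)` pointwise by a severity factor
≥ 1, leaving stations outside the segment and the throat location
untouched; closing the lumen is an error.

The axisymmetric solver consumes the **area-equivalent radius**
`r_eq(s) = √(A(s)/π)`, so concentric and eccentric variants of equal CSA
profile are hydraulically identical — CSA, not cross-section shape, is the
severity variable of this model. Centreline curvature is carried as
metadata only; the solver treats the graft as straight (see Limitations).

### Built-in case fixtures

Two case fixtures reproduce the published severity tables: narrowest CSAs
(OS/AS1/AS2) of 173/136/116 mm² (Case 1) and 165/130/93 mm² (Case 2). The
unstenosed baseline area is not published; it is back-computed per case as
the mean of CSA/(1 − printed fraction) over the three severities
(240.18 mm² and 239.44 mm²) and stored explicitly in the fixture. With
half-up integer rounding all six printed percent reductions (28/43/52,
31/46/61) round-trip exactly through build → CSA scan → percent reduction.
The stenotic extent and centre are not published; the fixtures default to a
45 mm extent (the span of ten 5 mm-apart measurement planes) centred 30 mm
from the inlet, between the 20 mm and 40 mm radiological measurement sites.
Both are free parameters of the fixture.

## Rasterization

The solver grid is a uniform staggered r–z grid with the radial spacing
chosen so the unstenosed wall falls exactly on a grid face
(`Δr = R₀ / ⌈resolution/2⌉`, `Δz = Δr`). Walls are represented stair-step:
a cell is fluid if its centre lies inside the lumen. The raster additionally
stores a per-cell *open fraction* (cut-cell area fraction), used only for
post-processing (CSA recovery from the raster is then second-order
accurate); the momentum and continuity discretisations use the binary mask.
Resolutions below 8 cells per baseline diameter, or throats thinner than
4 cells, are rejected.

## Flow solver

Incompressible Navier–Stokes with constant properties (defaults: blood at
high shear, ρ = 1060 kg/m³, μ = 3.5·10⁻³ Pa·s, Newtonian). Finite-volume
MAC discretisation in axisymmetric coordinates (metric weights `r` on
radial fluxes); a planar symmetric half-channel mode reuses the same code
with unit weights.

* **Advection**: mass fluxes are second-order central interpolations; the
  transported face value blends a fraction `upwind_blend` (default 0.15) of
  first-order upwind into the central average. Pure central transport is
  unstable here: the stenotic jet produces cell-Péclet numbers of order
  10², and the weighted cylindrical discretisation does not conserve
  discrete kinetic energy, so aliasing grows without bound. The bounded
  blend is the standard production-code remedy; computed gradients change
  by ~2% between blend 0.05 and 0.15.
* **Diffusion**: explicit, second-order, with reflection ghosts for
  tangential velocities at walls (no-slip enforced at the wall face; exact
  for the grid-aligned outer wall, first-order at interior stair steps).
* **Time integration**: explicit SSP-RK3. The time step defaults to an
  advective CFL bound of 0.5 at an estimated peak throat velocity (3× the
  mean throat velocity), capped by the explicit-diffusion bound
  0.2 h²/ν. A runtime monitor raises `CflError`/`NumericsError` on
  stability violation or non-finite fields.
* **Projection**: at every RK substage the provisional field is projected
  onto the divergence-free space through a pressure Poisson solve. The
  Poisson matrix is constant (assembled once per raster, sparse-LU
  factorised), so discrete continuity holds to machine precision in every
  fluid cell — the inlet/outlet flux mismatch in practice is ~10⁻¹⁴,
  against an acceptance threshold of 10⁻³.
* **Boundary conditions**: flat (uniform) inlet velocity matched to the
  flow rate through the binary mask; outlet Dirichlet static pressure
  (default 100 mmHg, 1 mmHg = 133.322 Pa) with zero-gradient velocity;
  no-slip rigid walls; symmetry at the axis. Constant inflow — the HM3
  artificial pulse is excluded.
* **Washout and sampling**: fields are sampled at a fixed cadence (default
  5 ms) after a washout of three domain pass-through times (or an explicit
  `washout_time`), for `sampling_time` seconds. Time averages weight all
  samples uniformly.

### Verification oracles

* Unstenosed tube at Re ≈ 15 converges to Hagen–Poiseuille: plane-pressure
  slope −8μQ/(πR⁴) and centreline velocity 2·v_mean, both within 2% at
  32 cells/diameter (measured ≈ 0.5%).
* Zero inflow relaxes to rest with uniform reference pressure.
* The 61%-stenosis drop lies inside the analytic bracket
  [B/2, 2(B + P)] with B = ½ρ(v²throat − v²inlet) (no pressure recovery)
  and P the unstenosed Poiseuille drop.
* Scaling: the drop doubles with flow at Re ~10 (viscous regime) and
  roughly quadruples at Re ~500–1000 through a tight stenosis (convective
  regime).
* Changing the outlet reference pressure shifts the pressure field by a
  constant and leaves velocities unchanged.
* A three-grid refinement study (16/32/48 cells/diameter) reduces the
  time-averaged pressure-gradient difference between the two finest grids
  to ~7·10⁻⁴ mmHg on the unstenosed tube, far below the 0.1 mmHg
  convergence criterion mirrored from the source protocol.

## Metrics

* **Planes**: 10 planes, 5 mm apart, centred on the narrowest station of
  the CSA profile (domain midpoint for an unstenosed tube; shifted inward
  if the span would leave the domain). Plane pressures are area-weighted
  means over the lumen cells of the nearest axial cell layer — robust on
  masked grids, no surface interpolation — then time-averaged.
* **Pressure gradient**: max plane mean pressure minus the aortic
  reference. Because the outlet holds the reference, this is in effect the
  recovered-pressure deficit of the most upstream plane.
* **Peak velocity**: by default the maximum of the *time-averaged* velocity
  magnitude over lumen cells; an `instantaneous` mode (max over samples) is
  available behind a flag. The time-averaged default matches reporting
  built on mean-velocity fields.
* **Reynolds statistics**: per cell-centre and component, mean over samples
  and RMS fluctuation with population normalisation 1/N (the published
  formula is typeset ambiguously; the accompanying text defines u′ as the
  root mean square of instantaneous minus mean velocity, which is what is
  implemented). TKE density is ½ρ(u′² + υ′² + w′²) exactly; in the 2D
  solver the out-of-plane component is identically zero (synthetic fixtures
  may populate it).
* **Integrated TKE**: the volume integral of TKE density over the whole
  graft lumen, in mJ. The integration subvolume behind published mJ values
  is not stated; the whole lumen is the default here.

## Statistics

Pearson product-moment R with two-sided P from t = R√(n−2)/√(1−R²) on n−2
degrees of freedom; α = 0.05; no multiple-testing correction. The nine
(severity × flow) cells of one case are pooled per correlation. Severity
enters both as narrowest CSA (mm²) and as ordinal rank (OS=1, AS1=2,
AS2=3), since "stenotic severity" is ambiguous between the two; both are
reported. A constant sample (e.g. identically zero TKE from a steady
laminar run) makes the correlation undefined: `pearson` raises, and the
correlation panel reports the pair as NaN / not significant instead of
fabricating R = 0.

## Synthetic data: what it does and does not emulate

The generator reproduces the *study conditions*: the severity tables, the
back-computed baseline calibre, device flows of 3.5/4.5/5.5 L/min, blood
properties, 100 mmHg reference, and a stenotic segment spanning the
measurement-plane window. It does not attempt patient-specific wall
irregularity, the bend-relief hardware shape, graft curvature, or the
U-shaped flow lateralisation that curvature induces. Passing tests
therefore demonstrate correct mechanics and bounded, severity- and
flow-consistent haemodynamics on idealised geometries — not agreement with
any specific patient's absolute values.

Analytic field fixtures (steady Poiseuille profile, single-frequency
sinusoid sampled over whole periods, seeded spatially-uniform Gaussian
fluctuations with three independent components, constants) give the metrics
stage closed-form expected values: u′ = A/√2 for the sinusoid, TKE density
= ³⁄₂ρσ² for the Gaussian fixture.

## Problem sizes and defaults

Default solver resolution is 32 cells per baseline diameter (≈ 3000 fluid
cells on a 100 mm graft); the severity sweeps and acceptance runs use 24
cells per diameter with 0.4–0.5 s of sampled flow after washout, which
keeps a full 9-cell sweep around two minutes on one CPU while every throat
remains resolved by ≥ 12 cells. Sampling can be extended (the
time-resolved protocol it mirrors used 6 s) and the resolution raised in
`SimulationConfig`; the mesh-independence study shows the reported
gradients are grid-converged well below 0.1 mmHg at these settings.

## Known limitations

* **No scale-resolving turbulence model.** The published analysis used
  large-eddy simulation on 5.9–8.2 million-cell patient-specific meshes;
  this package runs an under-resolved direct simulation on ~10³–10⁴ cells.
  At these Reynolds numbers the desk solutions are essentially steady, so
  computed TKE is near zero — the headline time-averaged pressure
  quantities (dominated by convective and viscous losses) are meaningful,
  absolute TKE magnitudes are not.
* **Straight, axisymmetric graft.** Curvature-induced secondary flow and
  the lateralisation of velocity, pressure and turbulence to the outer
  curvature are not represented; patient-specific absolute gradients
  (e.g. the largest published per-cell value) are out of reach by design.
* **Flat inlet profile.** The true pump–graft interface profile is unknown;
  only the flat assumption is implemented.
* **Rigid walls, Newtonian rheology, no artificial pulse** — all shared
  with the source protocol.
* The upwind blend adds numerical dissipation beyond the physical
  viscosity in the throat region; computed gradients sit near the
  no-recovery end of the analytic bracket.
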