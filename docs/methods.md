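# Methods

`tpmsflow` simulates perfusion of a vascular-like flow channel whose pore
space is carved out of a slab by a triply periodic minimal surface
(TPMS), and closes the loop from geometry through flow to scaffold
redesign: build the implicit geometry, solve steady laminar flow under a
venous pressure difference, locate the regions no nutrient fluid
reaches, prune them, and re-solve.

## Geometry model

TPMS families are represented through the standard trigonometric
approximation: a level set of a sum of plane-wave cosines,

    phi(r) = sum_k A_k cos( 2*pi*(h_k . r)/lambda_k + p_k ) = C,

with amplitudes `A_k`, integer reciprocal-lattice vectors `h_k`,
wavelengths `lambda_k` (mm) and phases `p_k`.  The Schwarz P surface used
as the pore-forming unit is the preset

    cos x + cos y + cos z = -0.5,

i.e. three unit axis terms and level constant −0.5.  The surface splits
space into two interpenetrating labyrinths; *network* mode keeps one of
them (by default the majority side, `phi − C ≥ 0`) as pore space, *sheet*
mode instead thickens the surface itself into solid (`|phi − C| ≤`
half-thickness, default 0.3 field units) and leaves both labyrinths
open.  Which labyrinth a physical scaffold uses is a design choice; both
rules are exposed.

The flow channel is a rectangular slab (default 66 × 30 × 10 mm) with
cylindrical ports (default diameter 3.08 mm, length 2 mm) on the two
x-faces, centred on the y–z midplane.  The TPMS lattice is centred on the
slab by default, which places a pore node on the port axis and
guarantees a percolating channel for the P-surface preset.

Voxelization classifies each voxel by the field sign at its centre — a
deterministic rule that a Monte-Carlo point-sampling oracle can check
directly.  Voxels are labelled `FLUID`, `SOLID`, `INLET`/`OUTLET` (the
port end caps, always on the grid boundary) or `EXTERIOR`; the solver
treats `EXTERIOR` like solid (no-slip) but porosity counts only
`FLUID/(FLUID+SOLID)` inside the slab, so trimmed material leaves the
model footprint rather than filling it.

Surfaces are extracted by marching cubes on the sampled field (level 0),
with one padding layer of below-level values when a watertight mesh is
wanted; area comes from the triangle mesh, volume from the divergence
theorem over oriented triangles.  On a 64³ sphere sample both agree with
the closed forms to well under 2%, and the errors shrink monotonically
under grid refinement.  The printed volume/area of the original scaffold
model are not reproduction targets: they depend on a unit-cell size and
wall-generation rule that are not recoverable, so quantitative geometry
checks use analytic fixtures instead (sphere, plane, Monte-Carlo
porosity).

The unit cell size is likewise a free parameter (`wavelength`, default
5 mm for the full-size slab — about 13 × 6 × 2 cells, consistent with a
multi-cell scaffold).

## Flow model

The fluid is Newtonian with constant properties (blood analog: density
1060 kg/m³, dynamic viscosity 0.005 Pa·s; temperature and shear-thinning
effects deliberately ignored).  Boundary conditions are fixed pressures
at the two port caps — inlet 12/13/14/15 mmHg against a fixed 11 mmHg
outlet in the study configuration — with stationary no-slip walls.
Pressures are specified in mmHg and converted with the exact factor
1 mmHg = 133.322 Pa.  At a characteristic 0.1 m/s in a ~3 mm channel the
Reynolds number ρvD/μ is ~64 (63.6 at D = 3.0 mm, 65.296 at the port
diameter 3.08 mm), far below the 2300 duct-transition threshold, so the
flow is laminar and no turbulence model is used; the inertial term is
retained.

The steady incompressible Navier–Stokes equations are solved with a
D3Q19 single-relaxation-time lattice-kinetic scheme on the voxel grid,
with a regularized collision step: the non-equilibrium part of each
population is projected onto its second-order (viscous stress) moment
before relaxing.  Plain BGK develops spurious high-order oscillations at
relaxation times near 1/2 — exactly the regime that blood's low
kinematic viscosity (4.7 × 10⁻⁶ m²/s) forces on sub-millimetre grids —
and the projection removes them while leaving the hydrodynamic limit
unchanged.  Walls use halfway bounce-back; the port caps impose the
reservoir pressure through the anti-bounce-back rule on the populations
arriving from outside the grid, which fixes the density half a link
beyond the cap (so the distance between the two pressure planes equals
the geometric port-to-port length).

### Unit mapping

The voxel spacing fixes the lattice length unit.  The time step is
chosen so the pressure drop maps to a target lattice density contrast
(default 0.03, i.e. ≤3% compressibility error between the ports); the
relaxation time that follows from the physical viscosity is clamped to
[0.505, 2.0].  If a run still diverges, the solver deterministically
halves the density contrast and restarts (up to four times).
Initialization is zero velocity on a linear pressure ramp between the
ports — or, for pressure sweeps, the warm-started equilibrium of the
previous solution, which changes only the iteration count, never the
converged state.

### Convergence

A run is converged when both (a) the relative L2 change of the velocity
field per 100 steps falls below 10⁻⁶ and (b) the relative inlet/outlet
mass-flux imbalance falls below 10⁻³ — the discrete form of monitoring
the flow difference between the two ports.  Fluxes are mass-weighted
(density × normal velocity × face area): a volumetric comparison would
show the lattice compressibility (~the density contrast) as a spurious
imbalance.  Runs that hit the iteration cap are returned flagged
`converged=False` with a warning; residual growth over ten consecutive
checks or a lattice speed above 0.3 raises a divergence error naming the
relaxation time.  The solver is bit-deterministic: fixed initialization,
fixed sweep order, no randomness.

### Validation

On a tube (R = 1 mm, L = 10 mm, 20 voxels across the diameter, 10 Pa
drop, blood properties) the solved centreline speed is within ~1.5% of
the Hagen–Poiseuille value 0.05 m/s, the least-squares slope of the
axial wall-pressure profile within ~1% of −ΔP/L, and the mass-flux
imbalance below 10⁻³; the remaining deficit is the physical entrance
loss of a pressure-driven finite tube plus the staircase representation
of the circular wall, and it shrinks under grid refinement.  A wide
rectangular slot reproduces plane Poiseuille flow within the same
tolerance, and doubling the pressure drop doubles the flux to within 2%
(Stokes linearity).

## Perfusion analysis

*Wall pressure* is defined on fluid voxels face-adjacent to solid (the
voxel analogue of a surface load), with the axial profile the mean wall
pressure per x-slice; on every converged run the profile is
non-increasing from inlet to outlet within 2% of the applied drop and
peaks in the inlet-most decile.  *Section velocity maxima* are taken
over y–z cross-sections, reported at the port mid-planes.  The
*realized Reynolds number* applies ρvD/μ to the mean inlet-cap speed.

*Dead zones* — "almost zero" flow is quantified as speed below 1% of the
mean pore speed, a scale-free threshold that tracks the perfusion
pressure.  Dead voxels are grouped by face connectivity (matching the
solver stencil); components below 8 voxels are discarded as numerical
noise.  The detector refuses unconverged fields, since stagnation is
then indistinguishable from an unconverged transient.

## Optimization (pruning)

A pruning plan removes either manually specified axis-aligned boxes (the
corner-trimming procedure applied to the original model) or detected
dead components, dilated by a 2-voxel margin so the stagnant boundary
skin and the pocket neck go with the pocket.  Removed voxels become
`EXTERIOR` by default (material cut from the footprint; `SOLID` backfill
is available), ports may never be touched, and a plan that severs
inlet–outlet percolation is refused.  Before/after reports at identical
boundary conditions are compared on dead-zone fraction, section maxima
and wall pressure; "fully perfused" means a residual dead fraction below
0.005.

## Benchmark fixtures

All geometry is generated in-repo and byte-deterministic:

- **tube / plane channel** — analytic validation fixtures (above).
- **cul-de-sac** — an 8 × 0.8 × 0.8 mm square duct with a
  0.8 × 2.0 × 0.8 mm side pocket behind a 0.5 × 0.2 × 0.4 mm neck, at
  0.05 mm spacing.  The pocket is connected (it fills with fluid) but
  lies off the inlet–outlet path, so it is a ground-truth dead zone;
  its voxel ids are recorded for recall measurement.  It is deep along
  y but short along the flow axis: a pocket's end faces enter the
  per-slice wall-pressure average at the stagnant pocket pressure, and
  keeping the axial span short keeps that composition effect inside the
  2%-of-ΔP band of the gradient check.  Solved at
  12 → 11 mmHg the pocket's mean speed is far below 1% of the channel
  mean, the detector recovers ≥90% of it, and pruning the detected
  component restores full perfusion without slowing the duct.
- **tpms_block** — periodic P-surface cubes for porosity and symmetry
  oracles; porosity is cross-checked against a seeded 10⁶-point
  Monte-Carlo sign-sampling estimate (agreement within ±0.01).
- **scaled scaffold slab** — the quarter-scale analogue of the
  66 × 30 × 10 mm channel: 16.5 × 7.5 × 2.5 mm, 0.77 mm ports
  (aspect-faithful), P-surface cell 1.25 mm, spacing 0.11 mm
  (7 voxels across the port, ~150k pore voxels).  The cell size is chosen so the venous pressure
  drops drive pore-scale flow at cell Reynolds numbers of order one —
  the same low-Re perfusion regime as the full-size scaffold — which a
  ~7-voxel pore throat resolves; a desk-scale run with the full-size
  5 mm cell would put almost the entire pressure drop across a handful
  of wide-open pores and demand an order of magnitude more grid to
  resolve the resulting jets.  Four solves (12–15 mmHg, warm-started)
  complete in minutes on one CPU.

What the fixtures do *not* emulate: the exact pore architecture,
unit-cell size and wall rule of the original scaffold (under-specified,
see above), elastic deformation of the channel walls (fluid–structure
interaction), pulsatile or interstitial flow, and any cell-biological
response.  Passing tests therefore demonstrate that the pipeline
reproduces the *qualitative* perfusion phenomenology — pressure-gradient
direction, monotone velocity response, dead-zone formation and removal —
and the *quantitative* closed-form benchmarks, not the printed field
magnitudes of any particular scaffold.

## Numerical choices and degenerate inputs

- Zero pressure drop is an exact fixed point: the solver returns a
  machine-zero field immediately.
- Port caps must lie on grid boundary faces (the pressure ghost plane
  sits half a link outside); violating domains are rejected.
- Fluid voxels unreachable from the ports are legal (they are dead-zone
  candidates) and evolve as closed cavities.
- An all-fluid box has no wall voxels; wall statistics then fall back to
  all fluid voxels with a warning.
- Tie-break in voxel classification: `phi − C = 0` counts as fluid under
  the `nonnegative` rule.
- The axis-permutation equivariance of the solver (permute the domain
  and the solution permutes) holds to iteration-accumulated round-off,
  ~10⁻⁶ relative.

## Known limitations

- The lattice Mach number is finite (density contrast default 3%), so
  pressure fields carry a compressibility error of that order; halve the
  contrast to trade runtime for accuracy.
- Staircase walls limit wall-shear accuracy at pore throats below ~5
  voxels; the port diameter and the narrowest pore should be resolved by
  at least 4–8 voxels (the builders warn otherwise).
- The regularized-SRT scheme loses accuracy (though not stability) for
  cell Reynolds numbers well above ~10; the shipped fixtures stay below
  that.
- Wall shear stress maps, non-Newtonian rheology, transient flow and
  fluid–structure coupling are out of scope.
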