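# Methods

This note records the modeling and numerical choices behind `cardiofield`:
what is simulated, which knobs matter, what the generated geometry does and
does not emulate, and where the known limitations are.

## Governing equations and normalization

The heart carries the parabolic–elliptic bidomain system with isotropic
per-subdomain conductivities; the torso is a passive volume conductor. The
membrane equation is used in normalized form: the surface-to-volume ratio β
and membrane capacitance per area Cm appear only as the product β·Cm, which
defaults to 1 so that the FHN rate constant k = 1000 s⁻¹ carries the time
scale and conductivities act directly as diffusivities (σ = 4 mS/m gives an
effective monodomain diffusivity of 2×10⁻³ m²/s and a plane-wave speed near
1.2 m/s for the ventricular parameter row — the physiological range). Both
constants are exposed in `SolverConfig` for dimensional studies.

The printed form of the coupled heart equations in the source literature has
inconsistent time-derivative signs; the solver implements the standard
bidomain weak form (a parabolic equation for Vm plus an elliptic
compatibility equation for Ve), which satisfies the physical requirement
that a depolarizing stimulus raises Vm.

Membrane kinetics: the sinoatrial node uses the self-oscillating FHN variant
(recovery current k·c2·v), all other tissue the Rogers–McCulloch variant
(recovery current k·c2·v·(Vm−B), which removes the nonphysiological
hyperpolarization of the original model). The registry stores the three
published regional parameter sets literally, including the ambiguous
Model 1 SAN value b = −0.30 exactly as printed; A and B are converted from
mV to V and conductivities from mS/m to S/m.

Worth knowing: integrating the Model 3 SAN row as a single cell gives a slow
relaxation oscillator — first action potential ≈ 0.88 s after the published
initial state (Vi = −60 mV), full period ≈ 2.9 s. Whole-heart SAN-driven
runs therefore need ≥ 1.2 s of simulated time to capture one full cycle.

## Geometry

The simplified heart is generated by labeling a tensor-product background
grid (each hexahedron split into six Kuhn tetrahedra, conforming by
construction) with analytic inside-tests at element centroids:

- ventricular myocardium: lower half of an ellipsoidal shell, outer
  semi-axes (45, 45, 65) mm, 10 mm wall; a 4 mm Purkinje shell nested
  inside it;
- atria: an ellipsoidal shell of outer semi-axes (50, 50, 40) mm with a
  3 mm wall, centered 30 mm above the base plane and cut at the insulation
  gap. The size is chosen so conduction path lengths (~120–150 mm from the
  pacemaker region around the shell) match real atrial activation;
- a 2 mm insulation gap slab separating atria from ventricles, crossed only
  by the AVN cylinder (radius 4 mm) sitting on the atrial annulus and the
  His cylinder (radius 1.5 mm) below it, which hands over to a cuboid
  bundle-branch bar that plugs into the septal Purkinje shell;
- the sinoatrial node: a 4 mm sphere flush with the right atrial wall;
- a 350 × 250 × 500 mm box torso; the bath also fills the ventricular
  cavity and the gap, so the heart surface is fully wetted.

Grid axes pass exactly through the gap planes and the bounding planes of the
small primitives, so thin features are resolved at any nominal spacing; a
locally refined band (default 1.5 mm) surrounds the AVN–His column, because
at σ = 0.5 mS/m the excitation front is ~0.4 mm wide and grids coarser than
about 2 mm exhibit discrete propagation block there. The His bundle is
deliberately narrow: a thick His loads the weak AVN front (source–sink
mismatch against a 20× conductivity jump) and blocks AV conduction.

Defaults: h_heart = 5 mm, h_torso = 40 mm (~176k tetrahedra embedded,
~32k heart-only). `refine()` performs uniform 1:8 subdivision with inherited
labels (volumes conserved exactly); regenerating at a smaller spacing is the
analogue of the "fine/finer" mesh settings and is what the convergence
experiment varies.

Heart rotation is applied in the frontal plane about the
anterior–posterior axis through the heart centroid (counterclockwise as
seen from the front), implemented as a rotation of the CSG labeling frame so
the conforming torso grid is untouched. On rotated grids the gap and septum
planes no longer align with the grid; erosion passes then remove any
labeled element that would bridge chambers through a shared node.

### Disconnected-chambers variant

`disconnected_chambers_config()` emulates a segmented anatomical heart whose
left atrium, right atrium and ventricles are three separate plain-myocardium
solution domains: the conduction-system primitives are removed, the Purkinje
shell is relabeled as ventricular muscle, and an interatrial septum slab
(bath) splits the atrial shell in two. Inter-chamber propagation then exists
only through the timed stimulus protocol (SAN site 2 ms, Bachmann's-bundle
site on the anterior interatrial roof 28 ms, AVN site at the septal
endocardium 150 ms; 2 ms each). Stimulus spheres default to
max(4 mm, 2·h_heart) so each event covers mesh nodes at any resolution;
amplitudes are expressed directly as transmembrane rate densities (default
200 V/s — comfortably suprathreshold; a physical "total current" cannot be
mapped into the normalized membrane form without committing to β·Cm, and
above threshold the exact value is immaterial).

## Time integration

Default scheme (`semi_implicit`), first-order in dt:

1. reaction: pointwise backward-Euler update of (Vm, v) per node, the
   recovery variable eliminated analytically and the remaining scalar
   equation solved by damped Newton (vectorized; non-converged nodes rerun
   with recursive half-steps). This remains stable for the stiffest
   published row (Model 1 SAN, k·c1 = 10⁶ s⁻¹) at dt = 1 ms;
2. diffusion: implicit solve of (M/dt + Kσi) Vm = rhs with the lumped mass
   matrix, factorized once;
3. elliptic: direct sparse solve for the combined extracellular/torso
   potential (shared interface nodes, ground row symmetrically eliminated),
   factorized once.

`fully_coupled` iterates steps 2–3 to a fixed point within each time step
(tolerance 10⁻⁹ relative), emulating a monolithic implicit solve; on test
problems the two schemes agree within 2 mV RMS. Default dt = 1 ms matches
the study protocol's sampling interval; the dt self-convergence test
verifies first-order behavior.

Initial conditions follow the published values: Vi = −60 mV at the SAN,
−85 mV elsewhere, Ve = v = 0.

## Feature extraction

P/QRS/T are located by windowed extremum search on a designated lead
(default II — the measurement lead is not stated in the source table), with
windows keyed to the stimulus protocol: the P window opens after the first
stimulus and closes at atrial depolarization completion (this keeps the
atrial repolarization deflection out of the P search), the QRS window spans
from the ventricular stimulus until shortly after ventricular
depolarization completes, the T window covers the rest. Stimulus pulse
intervals are excluded from both the peak search and the baseline estimate;
the baseline is the quiescent mean before the first stimulus. Wave duration
is the contiguous span around the peak above 10% of the peak deflection.

Chamber completion times: depolarization completion is the first time ≥95%
of the chamber's nodes have crossed −20 mV at least once (wavefront
coverage); repolarization completion is the first subsequent time ≥95% are
simultaneously back below. The cumulative reading matters: the atrial
action-potential duration (~85 ms at the Model 3 parameters) is shorter
than the atrial activation spread, so early tissue repolarizes before late
tissue activates and a simultaneous-fraction criterion would never be met.
The −20 mV threshold and 95% fraction are configurable; the protocol
experiment reports completion times at −20 and −30 mV and they agree within
10%.

## What the generated data does and does not emulate

The generated geometry reproduces the topology of cardiac activation — a
pacemaker, atrial spread, an insulated AV crossing with a slow node, a fast
ventricular conduction tree, endocardium-to-epicardium ventricular
activation, and a torso that turns the dipolar source into µV-scale surface
potentials with physiologically ordered timing. It does not reproduce any
specific anatomy: no fiber architecture (the model is isotropic by
assumption), no organs (lungs, bones, blood treated as uniform bath), no
atrial appendages or outflow tracts, electrodes on a box rather than a
human torso. Passing tests therefore demonstrate correct mechanisms and
orders of magnitude, not patient-level lead morphology; absolute lead
amplitudes are geometry-dependent and only their identities, polarities and
trends are asserted.

Known limitations:

- the conduction-system primitives adjoin the shell rims across the gap, so
  a small patch of insertion-site ventricular tissue can activate slightly
  before the His median time; the centroid-level activation ordering
  SAN → atria → AVN → His → bundle → Purkinje → ventricles is unaffected;
- first-order elements only; the element size (default 5 mm against an
  ~0.9 mm ventricular front width) inflates or deflates conduction speed by
  at most ~10% (measured on the bar surrogate between h = 5 mm and
  h = 0.5 mm), which is within the tolerance of every timing claim made;
- the box torso places the limb electrodes at the anterior corners; lead
  vectors are therefore only approximately Einthoven-triangular;
- one-sided P1 gradients make the outer-surface flux quadrature first-order
  accurate, so the "net current ≈ 0" check is exact only in its algebraic
  (weak-form residual) form.

## Problem sizes used by tests and the acceptance script

Tests run the embedded disconnected-chambers protocol (600 × 1 ms, ~176k
tets) once per session and a SAN-driven heart-only run (1.3 s, ~32k tets)
once per session; experiment-level tests use a coarser 6.5 mm/60 mm
configuration. The acceptance script runs the protocol study at the default
mesh and the SAN-driven whole heart for 1.3 s — together a few minutes on
one CPU. These sizes are the package's default study scale; all quantities
reported by the script are computed from those runs at run time.
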