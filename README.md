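# cardiofield

Forward cardiac electrophysiology on a simplified human heart–torso model:
a bidomain reaction–diffusion solver with modified FitzHugh–Nagumo (FHN)
membrane kinetics, producing transmembrane potential fields, body-surface
potential maps (BSPMs) and the standard 12-lead ECG.

It is aimed at people who want a transparent, fully scriptable forward-ECG
pipeline — from geometry generation through field simulation to waveform
features — without a commercial FEM package: method developers prototyping
inverse-ECG or BSPM algorithms, and students of cardiac modeling.

## Model

The heart is a continuum of two coexisting conducting media. With intra- and
extracellular potentials `Vi`, `Ve`, transmembrane potential `Vm = Vi − Ve`
and isotropic conductivities `σi`, `σe`, the normalized bidomain system
(surface-to-volume ratio × membrane capacitance absorbed into the time
scale, `β·Cm = 1`) is

    ∂Vm/∂t = ∇·(σi ∇(Vm + Ve)) − (I_ion − I_stim)
    0      = ∇·((σi + σe) ∇Ve) + ∇·(σi ∇Vm)

inside the heart, coupled to the passive torso volume conductor
`∇·(σb ∇V) = 0` (default `σb = 0.2 S/m`) with `V = Ve` on the heart–torso
interface, no-flux conditions on `Vi` at the heart boundary and on `V` at
the torso surface, and `V = 0` at the ground electrode (RL).

Membrane kinetics are two-variable FHN variants with `u = (Vm − B)/A`:

    I_ion = k·c1·(Vm − B)·(a − u)·(1 − u) + k·c2·v            (SAN, self-oscillating)
    I_ion = k·c1·(Vm − B)·(a − u)·(1 − u) + k·c2·v·(Vm − B)   (Rogers–McCulloch)
    dv/dt = k·e·(u − d·v − b)

Three published regional parameter sets (Models 1–3; per-subdomain values of
`a, b, c1, c2, d, e, A, B, k, σi, σe` for SAN, atria, AVN, His, bundle
branches, Purkinje network and ventricles) are built in; Model 3 is the
default. Leads follow Einthoven/Goldberger (`I = VL − VR`, …,
`aVR = (2VR − VL − VF)/2`) and the precordial leads are referenced to the
Wilson central terminal `VCT = (VL + VR + VF)/3`.

Discretization: linear tetrahedral finite elements on a feature-aligned
background grid labeled by constructive solid geometry (three nested
ellipsoidal shells, conduction-system primitives, box torso), lumped-mass
semi-implicit time stepping (pointwise implicit reaction, implicit
diffusion, direct sparse elliptic solve), with an optional fully coupled
fixed-point scheme. Coordinates are right-handed and in meters: +x toward
the anatomical left, +y anterior, +z cranial.

## Worked example

Run the stimulus-bridged whole-cycle simulation (isolated chambers driven by
spherical stimuli at the SAN site at 2 ms, Bachmann's bundle at 28 ms and
the AVN site at 150 ms — the protocol used for hearts whose chambers are
separate solution domains) and extract the ECG features:

```python
import cardiofield as cf
from cardiofield import ecg, solver, ionic, geometry

mesh = cf.embed_in_torso(geometry.disconnected_chambers_config())
layout = cf.place_electrodes(mesh)
protocol = solver.standard_protocol(mesh)
res = solver.run(mesh, ionic.get_model(3), protocol,
                 solver.SolverConfig(t_end=0.6),
                 ground_node=layout.ground_node)
traces = ecg.twelve_lead(res, layout)
f = ecg.extract_wave_features(traces, res, protocol=protocol)
print(f"P {f.p_amplitude*1e6:+.1f} uV  QRS {f.qrs_amplitude*1e6:+.1f} uV  "
      f"T {f.t_amplitude*1e6:+.1f} uV")
print(f"atrial depol/repol complete: {f.atrial_depol_completion*1e3:.0f} / "
      f"{f.atrial_repol_completion*1e3:.0f} ms")
print(f"ventricular depol/repol complete: "
      f"{f.ventricular_depol_completion*1e3:.0f} / "
      f"{f.ventricular_repol_completion*1e3:.0f} ms")
```

which prints (default mesh, ~3 minutes on one CPU):

```
P +11.3 uV  QRS +76.5 uV  T -32.5 uV
atrial depol/repol complete: 98 / 162 ms
ventricular depol/repol complete: 214 / 442 ms
```

The P, QRS and T amplitudes are the baseline-corrected extrema on lead II;
the T wave opposes the QRS because this drive repolarizes the ventricles
from endocardium to epicardium. The completion times are the instants at
which 95% of the chamber's nodes have been reached by the activation front
(depolarization) or have returned below −20 mV (repolarization), and fall
in the physiological range of a normal beat.

The same pipeline is scriptable from the shell:

```bash
cardiofield geometry --out mesh.vtu --electrodes electrodes.json
cardiofield simulate --disconnected --out run/
cardiofield experiment sensitivity --out sens/
cardiofield params --model 3 --dump
```

## Layout

| module | contents |
| --- | --- |
| `cardiofield.geometry` | heart/torso generation, CSG labeling, rotation, refinement, electrodes |
| `cardiofield.ionic` | FHN variants, Model 1–3 registry, single-cell integrator, nodal kinetics |
| `cardiofield.fem` | P1 tetrahedral assembly, boundary facets, flux quadrature |
| `cardiofield.solver` | bidomain + torso time stepping, stimuli, simulation results |
| `cardiofield.ecg` | electrode sampling, 12 leads, wave features, BSPM/epicardial maps |
| `cardiofield.experiments` | model comparison, rotation, convergence, sensitivity, protocol studies |
| `cardiofield.meshfiles` | ASCII VTU and Gmsh MSH 4.1 I/O, electrode layout JSON |
| `cardiofield.cli` | `cardiofield` command-line entry point |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
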