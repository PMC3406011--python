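# lvmech

Finite-element mechanics of the left ventricle (LV) with shear-induced
adaptive myofiber reorientation.

## The problem

The myofiber pattern of the normal mammalian LV (Situs Solitus, SS) is
remarkably invariant: fibers run in a right-handed helix near the
endocardium, circumferentially at midwall, and in a left-handed helix near
the epicardium, and they cross over between endo- and epicardium (a nonzero
transverse angle).  In people with complete mirror-image anatomy (Situs
Inversus Totalis, SIT) the pattern is *not* simply mirrored: it is normal
near the apex and inverted near the base, with a transition zone whose
location appears to vary between individuals — as does their measured
ventricular torsion.

A long-standing hypothesis holds that this architecture is not genetically
hard-wired but emerges from adaptive reorientation: fiber cross-fiber shear
during the cardiac cycle degrades fiber-matrix coupling, newly formed
connections fix the current (deformed, rigid-rotation-free) fiber direction
in the unloaded tissue, and the architecture converges to a state of low
shear and homogeneous workload.  `lvmech` implements this mechanism inside
a quasi-static finite-element model of LV mechanics coupled to a
lumped-parameter circulation, and uses it to predict the myofiber
architecture, torsion, and pump/myofiber function of one SS and three SIT
ventricles that differ only in the apex-base location `u_t` of the
fiber-pattern transition zone (BASE, MID, APEX).

## The model in brief

* **Geometry** — truncated-ellipsoid wall (wall volume 136 mL, unloaded
  cavity 44 mL), rotationally symmetric, meshed with 60 tri-quadratic
  hexahedra (6 radial x 1 periodic circumferential x 10 longitudinal);
  solved as an axisymmetric problem with unknowns (u_r, psi, u_z) so that
  torsion is retained.
* **Material** — total Cauchy stress `sigma = sigma_p + sigma_a f f`:
  Fung-type transversely isotropic, nearly incompressible passive law plus
  an active fiber stress from a contractile/series-elastic sarcomere model
  with length- and velocity-dependence, activated simultaneously
  everywhere with an 800 ms cycle.
* **Circulation** — two-compartment windkessel with diode valves; during
  isovolumic phases the cavity pressure is the Lagrange multiplier that
  holds the cavity volume constant (bordered Newton solve), during filling
  and ejection it couples implicitly to the venous/arterial flows.
* **Reorientation** — per cardiac cycle, every nodal fiber vector rotates
  by the fraction `1/kappa` (kappa = 5 cycles) of its angular gap towards
  `U e_f0 / |U e_f0|`, the deformed fiber direction with the rigid-body
  rotation removed (right polar decomposition `F = R U`), aggregated over
  end-diastole and five ejection instants.
* **Postprocessing** — phase-wise natural fiber strains
  `ln(lambda_end/lambda_begin)`, stroke work density `W_f` (area of the
  fiber Cauchy stress vs natural strain loop), maximum LV pressure, stroke
  volume, and section-wise torsion referenced to begin-ejection, evaluated
  the way tagged-MR torsion is (radially averaged slice rotation, shear-angle
  normalized).

See `docs/methods.md` for the full account, all parameter values and their
provenance, and known limitations.

## Worked example

Run the reduced-scale SIT simulation with the mid-ventricular transition
zone (a few minutes on one core), then inspect it:

```bash
lvmech run mid-reduced --out runs/mid-reduced
lvmech postprocess runs/mid-reduced
```

The run prints, at the end (numbers from an actual run of this command):

```
run 'mid-reduced' complete: SV 61.8 mL, p_lv,max 15.1 kPa, W_f 7.5 +/- 3.9 kPa; steady state at adaptation cycle None
```

meaning: after 4 fixed-fiber cycles and 5 reorientation cycles the LV
ejects 61.8 mL per beat at a peak cavity pressure of 15.1 kPa, and the
stroke work density averages 7.5 kPa (= kJ/m^3) with an inter-point SD of
3.9 kPa; five adaptation cycles are not yet enough to reach the 1%-per-cycle
steady-state criterion (the acceptance runs below use 15-40 cycles), and
`lvmech postprocess` shows the per-cycle trend — over these five updates the
mean stroke work density has already risen from 5.7 to 7.5 kPa and the
stroke volume from 49.5 to 61.8 mL, while the isovolumic-contraction strain
has shrunk from -0.067 to -0.028 (less pre-ejection fiber stretch-shortening
waste).  The
run directory contains `manifest.json` (every parameter echoed),
`hemodynamics.csv` (per-step pressures, volumes, flows, phase),
`adaptation.csv` (per-cycle function metrics: eps_ic, eps_ej, eps_ir, W_f
means and SDs, p_lv,max, SV), `torsion.csv` (section torsion before/after
reorientation) and `fibers.csv` (nodal helix/transverse angles, initial and
final).

Compare two runs:

```bash
lvmech run ss-reduced --out runs/ss-reduced
lvmech compare runs/ss-reduced runs/mid-reduced
```

What the full-length runs show, mirroring the study's findings: during
reorientation a nonzero transverse angle develops from the zero initial
condition, local and global function rise (more fiber shortening during
ejection, higher W_f, p_lv,max and SV) while the spatial spread of W_f
falls, torsion amplitude drops, and the three SIT runs converge to three
distinct continuous architectures whose torsion patterns shift along with
the transition-zone location — SS-like at the apex, inverted towards the
base.

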