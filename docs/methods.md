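# Methods

`lvmech` predicts left-ventricular (LV) myofiber architecture, wall
mechanics, torsion and pump function for the normal heart (Situs Solitus,
SS) and for mirror-imaged hearts (Situs Inversus Totalis, SIT) by combining
a quasi-static finite-element model of LV mechanics, a lumped-parameter
systemic circulation, and a shear-driven law of adaptive myofiber
reorientation.  This note documents the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic test
conditions do and do not show.

## Geometry and kinematics

The unloaded, passive stress-free LV wall is bounded by two truncated
ellipsoids of revolution sharing a flat base plane above the equator.  The
default wall volume (136 mL) and unloaded cavity volume (44 mL) describe a
small human / large dog heart; the axis ratios (endocardial 2.0, epicardial
1.5) and the truncation at half the endocardial long semi-axis are model
choices, not measured values, and every one of them is config-overridable.

The wall carries a normalized chart (u, v): u is linear in geodesic distance
along a shell meridian (-1 apex, 0 equator, +1 base plane) and v linear in
transmural distance (-1 endocardium, +1 epicardium).  Fiber distributions
and region definitions are expressed in this chart.

Geometry, fiber architecture, loading and boundary conditions are all
rotationally symmetric, so the discretization uses one periodic
circumferential element: a structured grid of 9-node biquadratic
quadrilaterals in the (R, Z) cross-section carrying three unknowns per node
— radial displacement u_r, azimuthal rotation angle psi, axial displacement
u_z — with the circumferential integral evaluated exactly (factor 2*pi).
This is algebraically identical to a mesh of 27-node tri-quadratic
hexahedra whose two circumferential faces are periodically identified, and
that hexahedral mesh (60 elements at the default 6x1x10 subdivision) is what
the mesh module builds and exports.  Retaining psi keeps torsion in the
kinematics.  The deformation gradient in cylindrical components is

    F = [[1 + u_r,R ,   0  , u_r,Z ],
         [ r psi,R  ,  r/R , r psi,Z],
         [ u_z,R    ,   0  , 1 + u_z,Z]],   r = R + u_r.

## Material

Total Cauchy stress is sigma = sigma_p + sigma_a f f, with f the deformed
fiber direction.  The passive part is a Fung-type transversely isotropic,
nearly incompressible solid,

    W = a0 [exp(a1 E:E) - 1] + af [exp(bf E_ff^2) - 1] + kappa/2 (J-1)^2,

defaults a0 = 0.5 kPa, a1 = 3, af = 0.01 kPa, bf = 60, kappa = 3000 kPa
(the penalty is set so that |det F - 1| stays below 2% everywhere at
end-systole of the full-resolution simulation).
The active part acts along the deformed fiber with magnitude from a series
arrangement of a contractile element (length l_c) and a series elastic
element:

    sigma_a = T0 f_iso(l_c) f_twitch(t_a, l_s) E_a (l_s - l_c),
    dl_c/dt = (E_a (l_s - l_c) - 1) v0,      l_s = lambda_f ls0,

with tanh^2 rise/decay twitch factors and a length-dependent twitch
duration t_max = b_tw (l_s - l_d).  Defaults: T0 = 250 kPa, E_a = 20 /um,
v0 = 7.5 nm/ms, ls0 = 1.9 um, tau_rise = tau_decay = 75 ms, b_tw = 150
ms/um, l_d = -0.5 um, cycle time 800 ms.  Activation is simultaneous
throughout the wall.  All coefficients are package defaults calibrated once
so that the converged normal run operates in the physiological regime
(cardiac output in the 5 L/min class, peak LV pressure ~110 mmHg); none are
literature constants, and the output manifest echoes every value used.
The sarcomere map l_s = lambda_f * ls0 uses a uniform unloaded sarcomere
length: the transmural prestretch gradient of real myocardium is not
modelled.

## Circulation and the cardiac cycle

A two-compartment windkessel (arterial C_art = 12 mL/kPa, venous C_ven = 60
mL/kPa, resistances R_art = 5, R_per = 140, R_ven = 2 kPa*ms/mL) closes the
loop; valves are ideal diodes.  Within a time step the valve/phase state is
frozen and switches at step boundaries (filling -> isovolumic contraction at
activation onset; IC -> ejection when p_lv reaches p_art; ejection ->
isovolumic relaxation when aortic flow reverses; IR -> filling when p_lv
falls below p_ven), so the Newton solve never crosses a valve discontinuity
and no conductance smoothing is needed.  Initial compartment volumes are
placed at the intended operating point (arterial 11.5 kPa, venous 1.4 kPa);
with physiological venous compliance the open-loop relaxation constant spans
tens of cycles, and initializing near the operating point is what lets a
handful of fixed-fiber cycles reach a hemodynamic steady state, mirroring
the usual practice in this model family.

Each time step solves quasi-static equilibrium with the cavity-volume
constraint V(u) = V_prev + dt * q(p_lv) as a bordered Newton system in
(u, p_lv); isovolumic phases are the special case q = 0, which holds the
cavity volume to the stated 0.01 mL.  Cavity volume is the disc-method
integral pi * int r^2 dz over the deformed endocardial meridian, closed by
the (axially fixed) base plane; the pressure load is applied through the
exact gradient and Hessian of this volume functional, so the follower-load
tangent is consistent.

## FE solution

Boundary conditions: u_z = 0 on the basal surface, psi = 0 on the basal
endocardial ring, u_r = psi = 0 on the long axis, traction-free epicardium.
Elements use 3x3 Gauss quadrature per cross-section element.  The material
tangent dP/dF is computed per quadrature point by central differences
(step 1e-6) around the exact first Piola-Kirchhoff stress; the geometric
coupling terms of the cylindrical kinematics are assembled analytically.
Newton iterations use the affine-invariant (natural) monotonicity test —
a trial step is accepted when the simplified Newton correction computed
with the current factorization contracts — which is robust to the large
transient residual spikes that the volumetric penalty produces; prescribed-
pressure solves fall back to automatic load substepping.  Convergence is a
relative residual of 1e-7.

The default time step is 2 ms for full-resolution runs and 8 ms for the
reduced study conditions (below); the contractile-element ODE is advanced
exactly per step (it is linear in l_c for frozen l_s).

With the default penalty, |det F - 1| stays below ~0.5% in diastole and
below 2% at end-systole on the full-resolution mesh (the apex-cap corner of
very coarse meshes can exceed this locally).  Full 3x3 integration of the
penalty makes coarse meshes overstiff (volumetric locking): the inflation
benchmark shows ~1% pressure error at 8 radial elements and grows on
coarser meshes, which is why the analytic cylinder comparison uses 8 radial
elements.  Stiff steps (large penalty, twitch onset) that defeat the damped
Newton are retried by approaching the volume target in substeps.

## Fiber fields

The helix angle alpha_h is the angle between the circumferential direction
and the fiber projection on the circumferential-longitudinal plane; the
transverse angle alpha_t the same with the circumferential-transmural
plane.  Fibers are directionless; vectors are canonicalized to a positive
circumferential component.

The SS distribution is a transmural cubic, alpha_h(v) = c0 + c1 v + c2 v^2
+ c3 v^3, default +70 deg endocardium, +15 deg midwall, -50 deg epicardium
(strictly decreasing), with zero transverse angle.  The slight endocardial
bias follows the pattern reported for the normal LV; exact coefficients are
a model choice.  The SIT initial field equals the SS field apical of a
transition zone and its inversion (alpha_h -> -alpha_h) basal of it; across
the zone of height h (default 0.3 u-units) the angle blends linearly in u,
and the zone centre line u = u_t + s*v tilts with slope s (default +0.25,
placing the transition more apically at the endocardium).  The three
headline SIT runs vary only u_t: +0.4 (BASE), 0 (MID), -0.4 (APEX); the
additional variants change s (0, 0.7) and h (0, 0.8) at u_t = 0.

## Reorientation

The unloaded fiber direction evolves towards the deformed fiber direction
corrected for rigid-body rotation: target = U e_f0 / |U e_f0| with U the
right stretch tensor of F.  Per cardiac cycle the target is aggregated over
end-diastole plus five equally spaced ejection instants, weighted by the
gap angle (instants with no drive carry no weight), and each nodal vector
is rotated towards its aggregate target along the great circle by the
fraction 1/kappa (kappa = 5 cycles).  Deformation is sampled at the nodes
by shape-function recovery averaged over adjacent elements; on coarse
meshes the corner extrapolation can produce a non-invertible average, and
such samples are treated as drive-free rather than extrapolated.  Boundary
nodes adapt like interior nodes — no constraint pins the orientation at
apex or base.

## Postprocessing

Local function per material point: natural fiber strains ln(lambda_end /
lambda_begin) over isovolumic contraction, ejection and isovolumic
relaxation, and the stroke work density W_f, the enclosed area of the fiber
Cauchy stress vs natural fiber strain loop (trapezoidal, explicitly closed;
positive for work-producing loops).  Statistics are volume-weighted means
and SDs over the wall excluding the basal-most and apical-most element
layers, where the essential boundary conditions and the apex cap dominate.
Global function: maximum LV pressure and stroke volume.

Torsion is evaluated the way rotation is extracted from tagged MR slices:
five equidistant axial levels between apex and base (inset by 25% of the
axial extent at either end, which keeps the apical slice above the apex
cap — the cap rotates essentially as a rigid block), rotation interpolated
from adjacent nodal
points along each transmural line and averaged transmurally, and each of
the four sections assigned the shear-angle torsion

    tau_i = (phi_apical - phi_basal) * rbar_i / d_i   [rad],

with rbar_i the mean reference midwall radius of the section and d_i the
level separation, referenced to zero at begin-ejection.  The radius scaling
makes sections with different radii comparable (it is the tangent-plane
shear angle); the rotation sense is right-handed about the apex-to-base
axis, so normal ejection twist is negative.  Two plausible alternatives —
rotation relative to the most basal slice, and unscaled adjacent-slice
differences — were considered and rejected: the first makes the basal trace
identically zero by construction, and both leave a purely geometric
apex-to-base amplitude gradient in a uniformly twisting wall, which would
mask the structural differences the section comparison is meant to expose.

## Study conditions and reduced runs

The full protocol per run: passive inflation to the venous pressure, 10
fixed-fiber cycles to hemodynamic steady state, then one reorientation
update per cycle.  The reduced study conditions used by the test suite and
the acceptance script are a 3x1x5-element mesh with dt = 8 ms; the SS run
uses 10 fixed-fiber cycles and 20 adaptation cycles, the MID run 40
adaptation cycles (its work-density heterogeneity peaks transiently around
cycle 5 before decaying, and its steady state arrives later than in the SS
run), and the BASE/APEX runs 15 (enough for the torsion pattern to
establish).  At this resolution the quantitative values carry discretization
error of a few percent and phase boundaries are quantized to the time step;
the qualitative findings — function rising and homogenizing under
reorientation, a transverse angle developing from zero, torsion amplitude
falling, and the torsion pattern shifting with the transition location —
are the quantities of interest and are stable under refinement.

## Synthetic fixtures

Analytic motions (rigid rotation, twist, incompressible radial inflation,
simple shear) provide closed-form deformation gradients for kinematics and
postprocessing oracles.  Synthetic MRT-like torsion sets emulate the format
of tagging-derived traces — four cyclic section traces with optional
additive Gaussian noise and an end-of-cycle drift mimicking tag fading (a
clean trace returns to zero at cycle end) — and exercise the comparison
plumbing only.  None of these fixtures model imaging physics, breath-hold
variability, or real myocardial microstructure, so passing them validates
the numerics, not physiological accuracy.

A consequence of the placeholder SS initial helix field worth flagging: with
a zero initial transverse angle the pre-adaptation SS twist concentrates in
the apex cap, below the imaging slices, so the slice-level torsion
amplitude of the SS run *rises* towards its physiological value during
reorientation instead of falling from an exaggerated one; the SIT runs,
whose transition zone does overshoot the initial torsion, show the decrease.
The acceptance outputs report both amplitudes per run so this is visible
rather than hidden.

## Known limitations

No myolaminar sheet mechanics or sheet reorientation; no right ventricle or
pericardium; no electrical activation delay (activation is simultaneous by
design); no growth or cavity remodelling; no transmural sarcomere-length
prestretch.  The circulation has no atrial contraction, valve inertia or
regurgitation.  Rotational symmetry excludes septal/free-wall differences.
Material and circulation coefficients are calibrated defaults, not fitted
to data; absolute stresses and work densities should be read as
model-internal quantities.
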