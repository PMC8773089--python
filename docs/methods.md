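# Methods

`ventriflow` reconstructs the geometry and motion of a left ventricle (LV)
from multi-view cine-MRI and simulates the systolic blood flow under that
prescribed motion, to quantify the outflow-tract (LVOT) obstruction caused
by hypertrophic cardiomyopathy (HCM).  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
phantom does and does not establish about real data.

## The moving-LV phantom

Patient images are replaced by a ground-truthed phantom: a thick-walled
truncated ellipsoid (cavity semi-axes `(a, b, c)`, truncation fraction
0.85, wall thickness 10 mm) with a septal bulge — hypertrophy modeled as a
Gaussian-shaped reduction of the cavity radius (default amplitude 12 mm,
angular width 0.7 rad, axial width 9 mm), giving a septal thickness of
22 mm, within the 16–25 mm range typical of HCM morphologies.  The default
cavity is auto-scaled so that EDV = 138 ml; with the default EF of 51%
these match a typical clinical HCM case.

**Motion law.** The ED shape is contracted by an affine map: in-plane
scaling `k(t)` and long-axis scaling `l(t) = k(t)^0.7` about the base
plane, with `k` chosen so the cavity volume follows a C¹ smoothstep from
EDV to ESV over systole (0.4 s of a 1 s beat) and back during diastole.
Because the map is affine, `V(t) = EDV·k²l` holds exactly, so ground-truth
volumes and displacements are closed-form.  Real ventricles twist and
contract inhomogeneously; the phantom deliberately does not, so passing
the recovery tests demonstrates the pipeline's resolution and consistency,
not its robustness to regional dyskinesis.

**Rendering.** Acquisitions mirror routine cardiac MRI: a short-axis stack
(1 mm in-plane, 8 mm slice spacing and thickness, 20 frames/beat) and
three long-axis single-slice views (2-/3-/4-chamber, 1 mm, 30 frames/beat),
with three tissue gray levels (blood 200, myocardium 90, background 20 —
typical bSSFP ordering), through-plane averaging across the slice
thickness, and seeded Gaussian noise (σ = 5).  The default bulge center is
placed midway between two short-axis slices, the configuration in which the
stack alone under-resolves the septum and long-axis views add information.
No MRI physics (k-space, banding, motion artifacts) is modeled, and all
series share t = 0 at end diastole (trigger alignment across series is
assumed).

## Fusion

All series are merged into an artificial 1 mm isotropic volume per frame on
the short-axis bounding box.  Each target voxel takes a distance-weighted
average of the nearest pixel of every slice, with a Gaussian weight
`w(d) = exp(−d²/2σ_w²)` (σ_w = 2 mm) and a 6 mm cutoff; "nearest pixel" is
nearest in full 3D distance with the slice collapsed to its mid-plane.
The kernel and cutoff are configuration: any smooth positive decreasing
weight is compatible with the scheme, and the defaults trade through-plane
blur (σ_w too large) against slice-to-slice seams (σ_w too small).
Temporal merging maps each of 20 equispaced target times to the
nearest-in-time source frame of each series, ties to the earlier frame.

## Segmentation, level sets, registration

The blood pool is segmented by 3-class Otsu thresholding, the largest
bright connected component, morphological closing and hole filling; the
epicardial mask adds the mid-intensity shell.  This is adequate for
phantom-grade contrast; clinical images would need the externally-produced
masks the interface also accepts.  The myocardium (epi minus endo) is
encoded as a signed-distance level set (negative inside the shell).

Frames are registered to the end-systolic reference (automatically chosen
as the minimum segmented cavity volume) with a two-level diffeomorphic
demons scheme on the level-set images (SimpleITK), Gaussian field
regularization σ = 2 mm, warm-started from the neighbouring frame.  Desk
runs register at 2 mm resampling — the level sets are smooth, so sub-voxel
accuracy survives the resampling; verification against known transforms
shows identity error 0 and a 3 mm rigid shift recovered to better than
0.1 mm at 1 mm resampling.  The displacement field maps reference points
to each frame; mapped reference surfaces give the volume curve by the
divergence theorem, with a cubic spline through the per-frame samples
providing values at arbitrary simulation times.

## Domain completion and meshing

The reconstructed cavity is completed with fully parametric templates
adapted to the annuli: a circle-swept aorta with Valsalva sinuses
(radius factor 1.4, height 20 mm) and a straight ascending segment
(40 mm) ending at the planar outlet Σ_out, blended to the basal
cross-section over a 12 mm LVOT taper; and a closed (coapted) mitral
leaflet surface spanning the saddle-shaped mitral annulus and bulging
6 mm into the ventricle.  The leaflet is immersed in the fluid domain,
not a mesh boundary; points that would protrude into the basal taper
(annulus saddle horns) are projected radially inward.  Annulus rings are
fitted with a least-squares plane + circle; the saddle height is the
amplitude of the `cos 2φ` out-of-plane mode.

The volume mesh is a structured swept-tube tetrahedrization: a
triangulated disk (rings of 6j nodes) extruded along the long axis, with
wedges split into tets by the index-ordering rule (conforming by
construction) and an apex cone closing the bottom.  Axial spacing is
`h_coarse` in the body and `h_fine` from 10 mm below the base through the
sinus top; in-plane resolution follows the local radius, which refines the
narrow LVOT automatically.  The desk preset uses h = 4.5/1.8 mm
(≈ 23k cells, chosen so a complete run fits a single workstation CPU in
minutes); the paper preset (h = 1/0.3 mm, Δt = 10⁻⁴ s) reproduces a
production resolution at far higher cost.  Mesh quality is certified per
ALE step by strict positivity of every cell volume.

**Displacement extension.** Registered endocardial displacement is imposed
on wall nodes below the base; the outlet is held fixed; the remaining
boundary (taper, root, ascending aorta) solves a Laplace–Beltrami problem
on the boundary triangulation with those Dirichlet data — the harmonic
blend is this package's choice for how template motion joins the imaged
ventricle.  A volumetric harmonic lift (factorized once on the reference
mesh) then defines the ALE map; the ventricle-subdomain volume change
tracks the image-derived cavity volume change to well within 2%.

## Flow model

Incompressible Navier–Stokes in ALE form, blood as a Newtonian fluid
(ρ = 1.06·10³ kg/m³, μ = 3.5·10⁻³ Pa·s).  Discretization: equal-order
P1/P1 tetrahedral elements with SUPG/PSPG stabilization plus a grad-div
term (τ_M with the standard 2ρ/Δt, 2ρ|a|/h, 12μ/h² scaling; τ_C = μ +
ρh|a|/2); first-order semi-implicit stepping with the convective velocity
frozen at `u^n − w` and every other term implicit, so each step is one
linear solve.  Wall velocity is imposed strongly at nodes (no-slip error
zero by construction).  The linear systems are solved by SuperLU,
refactorized every few steps and reused as a GMRES preconditioner in
between — the operator changes slowly along the beat, which keeps the
per-step cost at a triangular backsolve per iteration.

**Outlet.** A physiological systolic pressure waveform in the spirit of a
Wiggers diagram, `p_out(t) = 80 + 40·sin²(πt/T_sys)` mmHg, is applied as
normal traction on Σ_out; shape and values are configuration since no
specific patient waveform is modeled.  Directional backflow stabilization
`−(β/2)ρ(u·n)₋ u` with β = 0.2 is added on the outlet — required for the
stability of a truncated-domain outflow.  The initial condition is rest at
systole onset.

**Mitral valve (RIIS).** The closed leaflet is a Resistive Immersed
Implicit Surface: a penalty `(R/ε)·δ_ε(φ)·(u − u_Γ)` confined to a layer
of half-width ε around the surface, with δ_ε a compactly supported
parabolic bump of unit line integral and φ the distance to the moving
leaflet (advected with the extended displacement, so u_Γ equals the local
mesh velocity).  ε defaults to 3 mm on the desk mesh (0.75 mm at paper
resolution) respecting ε ≥ local mesh size; R = 10⁵ kg/(m²·s) is set by
the sealing contract — transvalvular flux below 1% of the outlet flux at
peak systole (a momentum balance gives penetration velocity ≈ Δp/R, which
at peak systolic dynamic pressures requires R of this order).  The layer
half-width must exceed the largest local node spacing — in-plane, not just
axial — or the sampled delta develops holes and the valve leaks through
them; the desk default respects that bound.  With R = 0
the solution is bitwise independent of the immersed surface.

**Verification.** Pressure-driven pipe flow reproduces the Poiseuille peak
velocity within 2% at 8 rings across the radius; a rest state under
uniform outlet pressure stays at rest to round-off; halving Δt changes the
peak outflow of a contracting-chamber benchmark by well under 2%; the
global mass audit (outlet flux vs −dV/dt of the moving domain) closes to
about 1% at desk resolution.

## Indicators

* **Volumetry:** SV = EDV − ESV, EF = 100·SV/EDV from the reconstructed
  curve; EDV is the t = 0 volume, ESV the minimum.
* **U(t):** maximum velocity magnitude over the nodes of the aortic
  subdomains (Valsalva root + ascending aorta) at each saved state.
* **U_thr and obstruction duration:** U_thr is the median of the saved
  systolic samples (the saved-frames median is the documented choice);
  the duration is the largest connected interval of the piecewise-linear
  interpolant with U > U_thr (strict), so it is not quantized to the
  output interval.  A sample lying exactly on the median splits the
  super-level set at a single point; such measure-zero gaps do not
  interrupt an interval.
* **Δp:** pressure minus the area-weighted outlet mean, in mmHg
  (133.322 Pa/mmHg); gauge-invariant by construction.
* **Septal line:** intersection of the boundary with the plane through the
  right-coronary-ostium proxy, the apex, and the septal center; the branch
  through the septum is parameterized by arclength normalized to the
  ostium→apex length.  On the phantom the ostium proxy sits on the aortic
  annulus ring (a deterministic analog of the real ostium), so the
  annulus marker falls at s = 0.  The intraventricular gradient is
  max(Δp) − min(Δp) on the line at the time of maximum gradient.
* **WSS:** t = μ(∇u + ∇uᵀ)n minus its normal component, with ∇u recovered
  at wall nodes by a local least-squares (patch) fit — P1 gradients are
  cellwise constant and superconverge under patch recovery.
* **Q-criterion:** Q = ½(‖W‖² − ‖S‖²) per cell, volume-averaged to nodes.
  Q carries units s⁻², the dimensionally consistent choice for a velocity
  gradient invariant.
* **Reynolds number:** Re = ρUD/μ with D the aortic-root (annulus)
  diameter and U the peak aortic velocity.

## Known limitations

The phantom's affine motion cannot produce regional hypokinesis, SAM of
the mitral valve, or trigger misalignment between series, and the
automatic segmentation assumes phantom-grade contrast.  Diastole, the
aortic valve leaflets, fluid–structure interaction and multi-beat
simulations are out of scope.  Desk-resolution flow fields resolve the
obstruction indicators but not the fine vortex cascade a 0.3 mm mesh
would capture; the Q-criterion fields at desk scale are therefore
qualitative.
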