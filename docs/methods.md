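# Methods

## Scope and model class

The package simulates bone-on-bone hip impingement as rigid-body
contact between watertight triangle meshes of the pelvis and femur,
rotating about a single fixed center (the femoral head center). Soft
tissues — labrum, cartilage, capsule — are deliberately absent, so
simulated limiting angles are upper bounds on physiologic motion, and
impingement incidence is if anything *under*-estimated relative to a
soft-tissue-aware model. A single rotation center is a known
simplification that degrades for protrusio or severely retroverted
sockets; the generator's buildable envelope (below) stays clear of
those morphologies.

## Synthetic anatomy

No patient imaging ships with the package; cohorts are drawn from a
constructive generative model in which each clinical parameter maps to
one geometric control.

**Femur.** Head sphere (radius 24 mm default) + neck capsule + oblique
shaft + condylar capsule, with the posterior condylar and epicondylar
axes aligned by construction so version measurements are well defined.
The cam deformity is a sphere centered on the neck axis whose
intersection ring with the tolerance-inflated head sphere (1.02 × r)
sits exactly at the requested alpha angle; below α = 45° no cam is
added and the neck radius r·1.02·sin α reproduces the requested angle
through the sphere–cylinder tangency relation α = asin(r_neck /
1.02 r). The 2 % tolerance mirrors how alpha is read off images (the
contour must leave the head circle visibly, not infinitesimally).

**Pelvis.** An acetabular cup shell — a spherical shell of inner
radius r_head + 1.0 mm (cartilage-free joint clearance) and thickness
5 mm, truncated at a coverage half-angle ψ — plus an AIIS prominence
capsule, an anterior iliac column to the ASIS, and a posterior column.
The cup pole is set by a fixed radiographic inclination of 40° and the
requested acetabular version; ψ is solved numerically so that the
*projected* lateral center-edge angle of the rim ring equals the
requested LCEA (the same coronal-projection measurement the package
applies to the output mesh). ψ is constrained to [15°, 85°]: below,
no rim remains to carry the AIIS construction; above, the socket
over-wraps (protrusio-like) and the construction self-intersects.
Requests outside this envelope raise a generation error naming the
constraint. The Hetsroni morphotype sets the lowest extent of the AIIS
prominence relative to the rim plane: +5 mm (type I), 0 (type II),
−6 mm (type III; not represented in the default cohort frequencies and
flagged as an extrapolation).

Meshes are extracted by marching cubes from exact-distance implicit
fields at a default pitch of 1.5 mm (a typical CT slice thickness;
configurable). Faces on the articular (lunate) surface are labeled at
generation time so joint congruence is never counted as impingement.

**Cohort defaults** are the anatomy of a surgical FAIS population:
α ~ N(67.13, 8.89²)°, LCEA ~ N(30.77, 6.55²)°, acetabular version ~
N(18.63, 6.34²)°, femoral version ~ N(14.19, 10.84²)°, AIIS type I
with probability 28/78 and II with 50/78. Draws are clipped to the
buildable ranges (clipping logged); infeasible combinations are
re-drawn, at most 100 times per patient. Covariate records carry the
*measured* anatomy of each generated mesh, which the round-trip tests
hold to within 2° of the request.

Constructive constants with no counterpart in the cohort parameters —
inclination 40°, neck-shaft angle 130°, head radius 24 mm, neck length
2 r, cam-sphere offset 0.35 r, AIIS capsule radius 6.5 mm and its
anterosuperior rim azimuth, column radii and endpoints — were fixed
once from orthopaedic reference ranges while checking that the
mean-anatomy hip is collision-free in the neutral stance and impinges
within the daily-living envelope in deep flexion, and are not exposed
as cohort dials.

## Frames, tilt and posture

The functional pelvic plane uses the bilateral ASIS and the scanner's
longitudinal axis (the classic anterior pelvic plane, which substitutes
the pubic tubercles for the scanner axis, is available as an option).
Pelvic tilt is a pure rotation about the FPP medio-lateral axis
*through the hip rotation center*: the exact pivot of sagittal tilt is
a modeling choice, and rotating about the joint center isolates the
angular effect — any translation component would confound tilt with
joint medialisation. Sign convention: **+τ = posterior** (the ASIS
move posteriorly).

Postures use flexion about the tilted pelvic lateral axis, adduction
about the floating anteroposterior axis, then internal rotation about
the femoral long axis. This matches the clinical description of the
protocol (fix flexion and adduction, sweep internal rotation) and is
validated against an independent Rodrigues-product oracle.

## Collision detection and the limiting-angle search

Narrow phase: a vectorized Möller triangle–triangle intersection that
also returns intersection segments; exactly coplanar pairs are resolved
by a 1e-9 mm signed-distance perturbation. Broad phase: a k-d tree
over static-triangle centroids with a centroid-distance bound, plus a
cluster-level prefilter over ~10 mm groups of femur triangles (the
femur subset rotates rigidly, so its clusters and radial bands are
precomputed). Verdicts are validated against an independent analytic
voxel-overlap oracle (0.5 mm grid on the generator's implicit solids)
outside a ±0.5 mm ambiguity band; the designed ~1 mm articular
clearance annulus is excluded from the oracle domain because it lives
permanently inside that band.

The swept angle (flexion, or internal rotation at fixed
flexion/adduction) advances from 0 in 1° steps up to the condition's
threshold (130° or 30°) and the first colliding bracket is bisected to
0.1° — both resolutions sit below mesh/landmark fidelity. If the start
posture already collides, the condition is recorded as impinged at 0°
and flagged, never raised: extreme synthetic anatomies must not abort a
cohort run. The contact point is the length-weighted centroid of the
largest intersection patch (patches = 3 mm single-linkage clusters of
segment midpoints; multiplicity retained on the result). One region
label per condition means regional counts always sum to the total
count.

## Regions

Region A is the wedge, in the sagittal projection about the acetabular
center, between the rays through the ASIS–AIIS and AIIS–rim inflection
landmarks; B is the arc anterior/inferior to the wedge down to the most
caudal rim point; C is the remaining posterolateral arc. Wedge
boundaries belong to A (conservative toward detecting AIIS involvement;
flip-able by users), and the B/C cut at the caudal rim belongs to B.
Sectors are built from the tilted pelvis so they ride rigidly with the
bone.

## Mixed models

The response is AIIS-region incidence (%), three rows per patient (one
per tilt), random intercept per patient. With a single variance ratio
θ = σ_b²/σ² the REML problem profiles to one dimension; per-patient
Woodbury identities give closed-form GLS quantities, and the outer
optimization is a bounded scalar search in log θ (boundary fits at
θ → 0 are flagged). Satterthwaite degrees of freedom come from the
delta method — numerical gradient of each coefficient's variance with
respect to (σ_b², σ²) against the inverse observed REML information
(central differences, relative steps 1e-6 and 1e-4) — and agree with
lmerTest to ~1e-5 relative on the frozen benchmarks. cAIC follows
Vaida–Blanchard: −2 × conditional log-likelihood at the BLUPs +
2(ρ + 1), with ρ the trace of the hat matrix of the mixed-model
equations; as σ_b² → 0, ρ collapses to rank(X) and cAIC to the
fixed-effects AIC. Deviance and BIC are computed from ML refits so
they are comparable across fixed-effect structures; REML is used for
all reported estimates. "Multivariate" in the model-comparison table
means multiple covariates with a scalar response (multivariable), which
is the only reading consistent with a single coefficient column.

The generative incidence simulator (for recovery studies) uses tilt
slope −0.8 %/deg, AIIS-type-I effect −6.7 %, femoral version −0.7,
acetabular version 0.06, LCEA 0.6, intercept placed to give 33.5 % at
neutral tilt with covariates at their means, random-intercept SD 15 and
residual SD 10. Raw responses are Gaussian by default; optional "clip"
mode truncates to [0, 100] and logs the truncated fraction (~4 % at the
defaults — enough to attenuate slope recovery, which is why truncation
is off by default), and "lattice" mode additionally snaps to the
100/12 grid of attainable incidences.

## Problem sizes and determinism

Every stochastic routine takes a single integer seed and is bit-
reproducible. The test suite exercises the geometry pipeline on a
20-hip cohort at the default distributions and 200/100-replicate
Monte-Carlo studies for the statistics layer; the acceptance script
uses a 12-hip geometric cohort and the same Monte-Carlo sizes. These
sizes give stable means (Monte-Carlo SE on the recovered slope
≈ 0.005) while keeping a full run in minutes on one core.

## What the synthetic cohort does and does not show

The generator reproduces the *mechanism* — cam/rim/AIIS geometry, its
parameter dependence, and the direction and rough magnitude of the tilt
effect — not any patient population's absolute incidence. Real hips
vary in ways the constructive model cannot (rim shape irregularity,
osteophytes, combined deformities, bilateral asymmetry), so passing
tests certify the algorithmic pipeline and its statistical estimators,
not clinical effect sizes. Absolute incidences from synthetic cohorts
should be read as model output on model anatomy; the mixed-model layer,
however, applies unchanged to incidence tables derived from real
segmented meshes with user-supplied landmarks.
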