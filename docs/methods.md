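# Methods

This note records the models, parameter defaults and numerical choices
behind the package, and what the synthetic validation study does and does
not demonstrate.

## Estimation model

The wall is treated as a thin membrane (no bending), loaded quasi-
statically by the diastole→systole pressure difference ΔP, with a
linearized (Hookean) response between the two imaged states. The
estimated quantity is the circumferential linearized Young's modulus per
centerline station,

    E_θ(ξ) = σ_θ(ξ) / ε_θ(ξ),

with radial and longitudinal stresses neglected. Strains between
diastole and systole in the ascending aorta are below ~10 %, which is the
regime where this linearization is conventionally accepted.

**Strain.** ε_θ is the relative change of the sectional radial contour
length L(ξ) = ∮ρ dθ between the two configurations of the *same material
contour*. Two section extractors exist:

* `section_mode="contour"` (default): the station plane cuts mesh edges;
  the crossed edges and interpolation weights define a material contour
  realized in every phase. The diastolic contour is exactly planar and
  the strain estimate is free of node-sampling wobble.
* `section_mode="nodes"`: nodes within a distance threshold of the plane
  (default 0.6 × the local axial edge extent) form the section. This is
  simpler and mirrors threshold-based selection on segmented surfaces,
  but on curved tubes it carries a small (≈±2 %) station-dependent
  contour-length wobble that is independent of mesh resolution; it is
  kept as an alternative and for contracts that need explicit node sets.

The contour length uses the radial integral ∮ρ dθ (trapezoid over the
ordered contour, exact for circles at any sampling), *not* the Euclidean
perimeter; the perimeter is available as an explicit alternative mode.
For near-circular aortic sections the two differ negligibly.

**Laplace (LH) stress.** σ_θ = ΔP·ρ̄/δ with ρ̄ the mean radial coordinate
of the *systolic* section. Using the systolic configuration matches the
inverse route (which also loads systole), and makes the two moduli
directly comparable. The curvature effect factor
m = (R0 − r)/(R0 − r/2) is reported per station and a warning is issued
where m < 0.9, where the thin-straight-tube assumption degrades.

**Inverse-engineering (IE) stress.** Membrane tension in a pressurized
membrane is statically determinate, so the systolic surface is loaded
with ΔP under a practically undeformable material (default 50 GPa; any
value above 10 GPa gives identical stresses, asserted to 0.1 %) and the
sectional stress is the contour average of the nodal maximal principal
stress. Solver: flat constant-strain triangles with the plane-stress
law, consistent nodal pressure loads along element outward normals,
direct sparse LU solve.

## Membrane solver details

* **Stabilization.** Pure membranes on curved open surfaces admit
  near-singular inextensional (ovalization) modes. Grounded springs along
  nodal normals (10⁻⁶ × mean stiffness diagonal) plus a tiny isotropic
  grounding (10⁻⁹) regularize them; the sphere and cylinder patch tests
  bound the induced bias well below 0.5 %.
* **Boundary conditions.** For tubes: the inflow ("valve plane") ring is
  fully fixed; the outflow ("arch plane") ring is constrained along its
  plane normal and radially free. Constraints are applied by penalty
  (10⁷ × max diagonal). An open surface under pressure with no ring
  condition is rejected as statically unsupported.
* **Forward (soft) solve.** The "systolic" validation surfaces come from
  a co-rotational Newton solve: element engineering strains are measured
  in each triangle's rotated frame against the baseline shape, the
  imposed material law sets the *Cauchy* stress proportional to that
  engineering strain on the *current* configuration, pressure follows the
  deforming surface, and the tangent includes the initial-stress
  (geometric) stiffness — which is also what physically stabilizes a
  tensioned membrane. This constitutive frame is exactly the one the
  estimator inverts (equilibrium stress of the deformed surface over
  engineering strain), and matches what a linear-elastic material in a
  commercial large-deflection solver effectively imposes. For a thin
  cylinder the converged radius is the closed-form fixed point
  r_dia/(1 − ΔP·r/(δE)), which the test suite checks against the solver.
  Load is applied in 3 increments with up to 30 Newton iterations each
  (relative residual 10⁻⁸; a stalled residual below 10⁻⁵ is accepted —
  the tangent omits the follower-load term, so convergence is linear near
  the end). A single linear small-strain solve is available via
  `linear=True`.
* **Poisson ratio.** ν = 0 for both solves. The inverse solve is
  equilibrium-determinate and ν-insensitive. For the forward solve, both
  end rings are axially restrained, so a nonzero ν would put the tube in
  plane strain and the recovered modulus would be the plane-strain
  modulus E/(1−ν²) rather than the imposed E; ν = 0 makes "imposed
  modulus" and "circumferential stiffness seen by the estimator"
  coincide, which is what a recovery study needs.

## Centerline

Marching-centroid extraction: starting from the inflow boundary-ring
centroid, the surface is cut by planes normal to the running direction;
each cut loop's **perimeter-weighted** centroid is the next sample (plain
vertex means are biased by ~0.1–0.2 mm because edge crossings cluster
around the structured mesh diagonals). Three correction passes re-cut
each sample with tangents estimated from its neighbours. The samples are
interpolated by a parametric cubic spline (an optional smoothing budget
in mm exists for noisy segmented surfaces) and resampled to
`n_stations = 50` equal-arc-length stations. The radius of curvature R0
comes from a least-squares circle fit over a sliding window spanning
about ±0.75 local section radii — wide enough that the fitted sagitta
dominates residual centroid noise; curvatures below 10⁻⁴ mm⁻¹ count as
straight (R0 = ∞). On the elbow fixtures the fitted R0 matches the
construction radius to < 1 %.

**End exclusion.** Stations within max(5 %, 0.75·r̄/L) of either end of ξ
are excluded from profiles. Boundary effects of the clamped valve ring
decay over a Saint-Venant length set by the *section radius* r̄, not the
tube length; a flat percentage under-masks short, wide tubes (on the
100 mm × r = 16 mm elbows the first station 6 mm from the clamp shows an
LH artifact of >13 % that has nothing to do with curvature).

## Morphing

Thin-plate-spline RBF interpolation of the displacement field sampled at
`n_source_points = 200` source nodes (Fibonacci-sphere-grid seeds
completed by farthest-point sampling), with an affine polynomial term so
rigid and affine motions are reproduced exactly. Correspondence: centroid
pre-alignment (closest-point pairing alone cannot see a rigid offset),
then 3 iterations of closest-point-on-surface pairing, then projection of
all nodes onto the target surface (on by default). Relative
regularization 10⁻⁸ stabilizes near-coplanar source sets. A compact
Wendland-C2 kernel is available for large meshes. On analytic targets the
morphed nodes land within 0.05 mm of the target surface and the morph
path reproduces the pre-mapped strain profile to < 0.5 % absolute.

## Units and defaults

| quantity | unit | default | note |
|---|---|---|---|
| coordinates | mm | — | all mesh I/O |
| pressure | mmHg at the interface | ΔP = 40 | converted once, 1 mmHg = 133.322 Pa |
| wall thickness δ | mm | 2.0 | same δ in LH and IE routes |
| stress | kPa | — | reported scale |
| modulus | MPa | — | reported scale |
| stations | — | 50 | equal arc length |
| strain floor | — | 10⁻⁴ | E masked (NaN) below it |
| rigid modulus | Pa | 5×10¹⁰ | inverse solve |

## Synthetic validation study

Geometries: straight cylinder and 45°/90° elbows (diameter 32 mm,
centerline arc length 100 mm — the arc-length reading reproduces the
design curvature factors m = 0.93 and 0.86 exactly, so it is adopted as
definitive), built at the mid-wall, 64 circumferential × 80 axial nodes
(≥ 50 nodes per section contour); and an aorta-like tube standing in for
a patient segmentation: arc radius ≈ 83 mm over 110° (ascending-portion
m ≈ 0.87–0.91, matching the ~0.89 reported for real ascending aortas), a
15 % root bulge, a gentle distal taper (25 % total radius variation) and
small seed-controlled smooth perturbations, 64 × 100 nodes, arc length
160 mm.

Fields: homogeneous 0.5 / 1.75 / 3.0 MPa and a proximal/distal step
2.0 → 0.5 MPa at ξ = 0.5 (right-closed: the transition station itself is
distal). Loading: ΔP = 40 mmHg, δ = 2 mm, valve ring fixed, arch ring
radially free.

What passing the study shows: the estimation chain (mapping, centerline,
sectional strain, both stress routes, masking, metrics) recovers imposed
moduli on smooth, noise-free, tube-topology surfaces with errors from
method approximations only — curvature bias of the Laplace route,
membrane boundary layers, section discretization. What it does not show:
robustness to segmentation noise and imaging artifacts, real aortic wall
thickness variation, branches, non-tubular topology, hyperelastic or
anisotropic behaviour, or inertial loading. The step-field case also
quantifies the intrinsic smoothing of sectional slicing: stations within
about one station spacing of the step blend the two moduli, which
dominates that case's RMSPE.

Observed at the defaults (full resolution, one CPU, a few minutes):
cylinder max recovery error ≈ 0.1 % (both routes); 90° elbow max ≈ 3.1 %
(LH) / 1.4 % (IE); aorta-like homogeneous RMSPE ≤ 0.4 % (IE); step field
RMSPE ≈ 4–6 % (IE). The acceptance script recomputes all of these.

## Known limitations

* Strain is circumferential only and single-valued per slice; no
  longitudinal strain, no intrados/extrados differentiation.
* The membrane model omits bending: clamped-end boundary layers differ
  from shell solutions, hence the geometry-aware end mask.
* The LH route inherits the thin-wall, low-curvature assumptions; its
  errors grow as m falls (warned below 0.9).
* Patient-specific wall thickness is a single user-supplied δ; both
  stress routes (and hence E) scale as 1/δ, so δ uncertainty propagates
  one-to-one (tested).
* The aorta-like tube is a geometric stand-in, not a segmented patient
  anatomy; recovery numbers on it are better than on real segmentations.
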