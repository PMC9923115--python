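# aortastiff

Non-invasive, image-based estimation of **local arterial wall stiffness**.
Given segmented luminal surface meshes of a vessel (typically the ascending
aorta from ECG-gated CT) at two or more cardiac phases, a diastole–systole
pressure difference ΔP and a wall thickness δ, the package maps the
surfaces onto a common mesh, measures the circumferential strain of every
cross-section along the vessel centerline, evaluates the wall stress by two
independent routes, and reports the linearized Young's modulus as their
ratio — a per-slice stiffness profile and nodal map instead of a single
global distensibility number.

Intended users: cardiovascular-biomechanics researchers working with
dynamic (multi-phase) vessel segmentations who want a fast, local,
simulation-light stiffness estimate, plus a fully synthetic validation
harness to quantify how well the estimator recovers known moduli.

## Method

1. **Mapping** — the diastolic (0 %) surface Σ_dia is morphed onto each
   later phase with thin-plate-spline RBF interpolation of a sparse
   displacement field (source points spread over the surface, iterated
   closest-point correspondence, final projection), so node *i* is the
   same material point in every phase.
2. **Strain** — the centerline ξ of Σ_dia is extracted (marching plane
   cuts); for each station the cross-sectional contour is measured in both
   configurations and the circumferential strain is the relative change of
   the radial contour length

       L(ξ) = ∮ ρ(θ) dθ,   ε_θ(ξ) = (L_sys − L_dia) / L_dia.

3. **Stress** — two routes:
   * *Laplace hypothesis (LH)*: thin-wall hoop stress σ_θ = ΔP·ρ̄/δ with
     ρ̄ the mean systolic section radius; valid where the curvature effect
     factor m = (R0 − r)/(R0 − r/2) ≈ 1 (R0 = centerline radius of
     curvature).
   * *Inverse engineering (IE)*: wall tension of a pressurized membrane is
     statically determinate, so the systolic surface is loaded with ΔP as
     a near-rigid membrane (constant-strain-triangle FE solver built in)
     and σ_θ is the ring average of the nodal maximal principal stress.
4. **Stiffness** — linearized Hooke ratio per station:
   E_θ(ξ) = σ_θ(ξ)/ε_θ(ξ), for both routes.

The synthetic validation study ships with the package: a straight
cylinder and 45°/90° elbows (diameter 32 mm, centerline length 100 mm,
δ = 2 mm) plus a curved, radius-varying aorta-like tube, pressurized at
ΔP = 40 mmHg under homogeneous (0.5 / 1.75 / 3.0 MPa) or proximal/distal
step (2.0 / 0.5 MPa) modulus fields by the built-in forward membrane
solver, then fed back through the estimator to measure parameter-recovery
errors (per-station relative error RErr and its root-mean-square RMSPE
along ξ).

## Worked example

Recover a known modulus on the cylinder fixture:

```python
import numpy as np
import aortastiff as ast

spec = ast.TubeSpec()                      # d=32 mm, L=100 mm, delta=2 mm
dia = ast.make_tube(spec)
cl = ast.compute_centerline(dia, inflow_hint=np.array([0.0, 0.0, 0.0]))
field = ast.StiffnessField(kind="homogeneous", e_h_mpa=0.5)
sys_mesh = ast.forward_inflate(dia, field, cl, dp_mmhg=40.0)

phases = ast.assemble_phase_set(dia, [sys_mesh], labels=["sys"])
prof = ast.stiffness_profile(phases, cl, ast.PressureSpec.from_dp(40.0),
                             thickness_mm=2.0, systolic_label="sys")
print(f"mean strain        : {np.nanmean(prof.epsilon):.4f}")
print(f"mean sigma_LH (kPa): {np.nanmean(prof.sigma_lh_kpa):.2f}")
print(f"mean E_LH (MPa)    : {np.nanmean(prof.e_lh_mpa):.3f}")
print(f"mean E_IE (MPa)    : {np.nanmean(prof.e_ie_mpa):.3f}")
rep = ast.validate_against_reference(prof, field, "IE")
print(f"IE RMSPE (%)       : {rep.rmspe_percent:.2f}")
```

prints

```
mean strain        : 0.0931
mean sigma_LH (kPa): 46.62
mean E_LH (MPa)    : 0.501
mean E_IE (MPa)    : 0.500
IE RMSPE (%)       : 0.00
```

i.e. a ~9.3 % systolic hoop strain, a ~46.6 kPa hoop stress on the
inflated radius, and recovery of the imposed 0.5 MPa by both routes.

The same pipeline runs from the shell. For a pre-mapped diastole/systole
pair (e.g. forward-simulation output):

```bash
aortastiff generate --outdir fixtures            # write the study fixtures
aortastiff stiffness fixtures/cylinder_dia.vtp fixtures/cylinder_sys_H0.5.vtp \
    --no-morph --dp 40 --outdir out              # maps + profiles + summary
aortastiff validate                              # full study + bound checks
```

For raw (unmapped) patient-style phases, omit `--no-morph` and pass all
phase surfaces; the phase with the highest strain is selected as systole,
and clinical pressure records can be given as `--pressures 82-120`.

## Limitations

Circumferential strain only (no longitudinal strain, no inner/outer
curvature differentiation); linearized elasticity (no hyperelastic or
anisotropic identification); quasi-static loading; one modulus value per
centerline slice. See `docs/methods.md` for the model assumptions,
parameter defaults and numerical choices in detail.
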