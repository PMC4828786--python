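# Methods

## Model

### Balloon membrane

The balloon is treated as an axisymmetric hyperelastic membrane: a
meridian (z, r) revolved about the catheter axis, discretised into
conical-frustum elements.  Element stretches are the meridional
λ_m = L/L₀ and circumferential λ_θ = r_mid/R_mid ratios; the film is
taken fully incompressible in plane stress, λ₃ = 1/(λ_m λ_θ), so the
through-thickness stretch never enters as an unknown.  Bending stiffness
is neglected (membrane theory): the film is 0.09 mm thick at a 11.5 mm
radius, t/r ≈ 0.008.

The strain energy density is a third-order Ogden form in principal
stretches,

    U = Σᵢ 2μᵢ/αᵢ² (λ₁^αᵢ + λ₂^αᵢ + λ₃^αᵢ − 3),

with the volumetric terms (1/δᵢ)(J_el − 1)^{2i} omitted by the solver
(incompressibility is enforced kinematically; δ₂ = δ₃ = 0 in the shipped
coefficient set anyway, and the membrane through-thickness response is
second-order).  The shipped balloon coefficients are

    μ = (−4715.57, 2480.94, 2479.35),  α = (4.89, 6.90, 1.13),
    δ = (1.38, 0, 0),  ν = 0.45 (metadata only)

interpreted in **MPa**.  The source table does not state the stress
unit; MPa is the physically consistent choice: the initial Young's
modulus 3Σμᵢ ≈ 0.73 GPa is the right magnitude for a PET/Nylon balloon
film, and predicted inflation pressures then fall in the bench range of
a few hundred kPa, whereas kPa would make the balloon ~1000× too soft.
The assumption is isolated behind the material's `units` tag.

Uniaxial reduction (incompressible, λ_transverse = λ^{−1/2}):
Cauchy σ = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − λ^{−αᵢ/2}), nominal σ/λ.  Tensile data
are taken in engineering (nominal) stress and strain, the standard
convention for dumb-bell output.

### Volume-controlled loading

The injected contrast is incompressible, so "fluid exchange" loading
reduces to the constraint V(x) = V_target with the cavity pressure P as
the Lagrange multiplier:

    ∇E(x) − P ∇V(x) = 0,   V(x) = V_target,

where E is the total strain energy (plus contact penalty energy) and V
the frusta-quadrature volume of the revolved meridian.  The end nodes
are pinned radially at the shaft radius and free axially (one axial dof
anchors the rigid translation).  Loading follows the pump schedule
V(t) = V₀ + V̇·t (default 40 ml/h, one sample per 15 s), with V₀ the
stress-free reference cavity volume unless specified.

### Wrinkling (tension field)

Membranes cannot carry compression.  The relaxed (tension-field) energy
has four branches — taut; hoop-wrinkled (uniaxial along the meridian at
natural transverse contraction); meridionally wrinkled; fully slack —
separated by the boundaries λ_θ = λ_m^{−1/2} and λ_m = λ_θ^{−1/2}
(zero trial hoop / meridional stress).  The hard relaxation is only C¹,
and converged inflation states sit *on* the wrinkling boundary, which
defeats Newton-type solvers.  The branches are therefore blended by a
smooth partition of unity in the stretch-space distance from the
boundaries (sigmoid switches, band `wrinkle_smoothing = 5e-4` stretch
units).  The blend is exact on the boundaries themselves — adjacent
branch energies and gradients coincide there, so the stress-free
reference is exactly stress-free — and its deviation from the hard
relaxation decays like exp(−gap/band): a taut element 1 % of stretch
away from the boundary is affected at the 10⁻⁹ level.  Elements inside
the relaxed regime are flagged `slack`; reported inflation curves start
at the first fully taut state.  A tiny quadratic regularisation
(`regularization = 1e-8`·μ₀) keeps fully slack zones positive definite.

### Contact with the implantation-site phantom

The phantom is a coaxial thin-walled cylinder.  Contact is frictionless
and radial: where the balloon radius exceeds the phantom's bore, a
contact pressure acts, derived from a penalty potential with reference
tributary areas so the full residual remains the gradient of one scalar
potential.  A *compliant* phantom responds with the thin-wall radial
stiffness k = E·t/r_in² (from the vessel module), i.e. the contact
pressure equals the phantom's linear Laplace pressure at the attained
radius — that identity is the coupling check.  A *rigid* phantom, and
the phantom's constrained end bands, use a penalty auto-scaled to
10³ × the membrane radial stiffness and escalated ×10 until penetration
is below 10⁻³·r_phantom.  The phantom's axial wall coupling is not
modelled (local Winkler response); its end bands are held at the
reference radius, as in the bench fixtures.

### Solution strategy

Each volume target is solved by a damped Newton iteration on the
augmented system, with the Jacobian built by coloured finite differences
(the meridian is a chain, so six perturbed residual evaluations suffice
regardless of mesh size) and an analytic bordered row/column for the
constraint and pressure.  Convergence: max nodal residual ≤ 10⁻⁸ of the
characteristic force E₀·t·L̄, volume error ≤ 10⁻⁹ relative.  Where
Newton's convergence radius collapses (the wrinkled low-pressure toe
just above the stress-free volume), the step falls back to a
trust-region SQP minimisation of the same energy under the same
constraint (exact coloured-FD Hessian, analytic volume gradient and
Hessian); the KKT point is accepted under a looser force-balance check
and the per-state diagnostic `residual_rel` records it (observed
~10⁻⁵).  Continuation advances in steps of ≤ 0.25 ml with automatic
halving.  The solver contains no randomness.

## Analysis equations

Thin-wall (Laplace) block, taken literally with r the inner radius:
σ_θ = P·r/t, ε = (r − r_in)/r_in, r = √(V/(π·l)),
D = (V_last − V_first)/((P_last − P_first)·V_in) (endpoints of the
record by default; a windowed variant exists), E = σ_θ/ε at the
record's final state.  The small-strain closed form D = 2r/(E·t)
(per-MPa, converted to mmHg⁻¹) ties D and E together; the two agree on
synthetic records to <1 % at ≤0.5 % strain, and the finite-strain bias
of the linear formulas grows monotonically with strain (≈ε relative).
The compliance generator defaults to a uniform cylinder (no end bands)
because these formulas assume one; the banded response (linear radius
taper over each band) is used by the contact solver and validated
against quadrature.

Imaging: calibration w = b₁,real/(2 b₁,image) + b₂,real/(2 b₂,image)
(mean of the two single-pair ratios, halving beam-distortion error);
contours are traced column-wise at sub-pixel resolution by linear
interpolation of the threshold crossing, with the symmetry axis fitted
by least squares and the radius taken as the half-width; volumes by the
same frusta quadrature as the solver; the "central section" is the
axial midpoint of the contour bounding box, widths averaged over AP and
LAT.

Metrics: curves are compared "at equal volume" by linear interpolation
onto a 200-point uniform volume grid over the overlap of the two volume
ranges (the pairing rule is the package's choice); RMSE_P and RMSE_d
are root-mean-square differences on that grid, RMSE_P also reported as
an unrounded percentage of the peak experimental pressure, and RMSE_d
flagged against the 0.5 mm fluoroscopy pixel.

## Synthetic bench

The generators emulate the bench instrumentation: pressure noise is
additive Gaussian (default 10 mmHg) followed by quantisation at the
0.2 atm manometer resolution; diameters are quantised at the 0.5 mm
isotropic fluoroscopy pixel; tensile and compliance records take
additive Gaussian noise.  Cyclic tensile tests insert per-cycle residual
strain offsets, defaulting to a 3 %→5 % ramp over ten cycles to 10 %
strain — the residual-strain range typical of this balloon film class —
so the unloading branch crosses zero stress exactly at the offset.
Projections are rendered as anti-aliased silhouettes with four bead
markers at known spacings, Gaussian blur and intensity noise.

What the generators do *not* emulate: the forward model generates the
"experimental" curves, so model-form error (real balloon folding,
non-uniform film thickness, elastoplastic drift between repeat
inflations, phantom viscoelasticity) is absent.  Passing round-trip
tests therefore demonstrates the correctness and internal consistency
of the numerics and analysis chain, not agreement with physical bench
data.

## Problem sizes and numerical choices

Default meshes: 200 meridian elements (sensitivity-checked: P at fixed
V changes <0.5 % from 200 to 400 elements); tests and examples use
60–120 elements where full resolution is not the point.  The
closed-form verification inflates a long cylindrical balloon (heads
5 % of length, shallow shoulders at 10 mm shaft radius so the membrane
stays taut) to hoop stretches 1.0–1.15 and compares the mid-section
pressure with the analytic incompressible-Ogden cylinder,
P = σ_θ·t₀/(r₀·λ_θ²·λ_z); agreement is ~0.1 % of the peak pressure
(the comparison is normalised by the peak of the range because it
includes the P = 0 point).  Ogden fitting uses variable projection
(the model is linear in μ), five deterministic α seeds, and a
Drucker-type stability filter (Σμ > 0, monotone uniaxial Cauchy stress
on the data range); fits are non-unique, so round-trips are asserted on
the predicted stress curve, not the parameters.

## Limitations

* Quasi-static axisymmetric statics: no folding/crimping from a
  deflated state, no dynamics, no non-axisymmetric buckling modes.
  Inflations start from the stress-free nominal geometry.
* The wrinkled low-pressure toe (between the stress-free volume and the
  first fully taut state) is resolved only to ~10⁻⁵ relative force
  balance and within the smoothing band of the tension-field blend;
  pressures there are a few mmHg uncertain.
* The phantom is a local thin-wall spring: no axial wall coupling, no
  3D end effects beyond the linear band taper, linear elasticity only
  (flagged above 10 % hoop strain).
* The balloon film is hyperelastic; the residual strain seen in cyclic
  tests is measured descriptively but not simulated (no elastoplastic
  law).
* Contact is frictionless and radial; no balloon burst prediction.
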