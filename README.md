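# balloonmech

Membrane mechanics of non-compliant valvuloplasty balloons, at desk
scale.

During balloon aortic valvuloplasty a stiff, high-pressure balloon
(PET/Nylon-class film, nominal diameter ~23 mm, nominal pressure ~4 atm)
is inflated across a stenosed aortic valve.  Bench validation of a
computational balloon model compares pressure–volume (*P–V*) and
diameter–volume (*d–V*) curves from volume-controlled inflation — free,
and inside a compliant cylindrical phantom that mimics a calcified
aorta — against the simulation.  `balloonmech` implements that entire
workflow for engineers developing or validating such device models:

* **Axisymmetric hyperelastic membrane solver** — the balloon is an
  incompressible Ogden membrane in plane stress, discretised along its
  meridian; inflation is volume-controlled (the cavity pressure *P* is
  the Lagrange multiplier of the constraint *V(x) = V*target), with
  smoothed tension-field wrinkling and frictionless radial contact
  against a thin-walled elastic cylinder.
* **Materials** — Ogden strain energy
  *U = Σᵢ 2μᵢ/αᵢ² (λ̄₁^αᵢ + λ̄₂^αᵢ + λ̄₃^αᵢ − 3) + Σᵢ (1/δᵢ)(J_el − 1)^{2i}*,
  uniaxial reduction σ = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − λ^{−αᵢ/2}), non-convex
  least-squares fitting to tensile data, isotropy and residual-strain
  analysis of cyclic tests.
* **Vessel / phantom analysis** — the thin-wall (Laplace) block
  σ_θ = P·r/t, ε = (r − r_in)/r_in, r = √(V/(π·l)), distensibility
  D = ΔV/(ΔP·V_in) and Young's modulus E = σ_θ/ε from compliance
  records.
* **Fluoroscopy-style imaging** — bead-marker calibration
  w = b₁ᵣ/(2b₁ᵢ) + b₂ᵣ/(2b₂ᵢ), sub-pixel silhouette contours,
  solid-of-revolution volumetry, biplane central-diameter measurement.
* **Validation metrics** — RMSE_P and RMSE_d at equal volume on a
  common grid, and RMSE as a percentage of the peak pressure.
* **Synthetic bench** — seeded generators for tensile curves, compliance
  records, noisy inflation experiments and biplane projections, so every
  analysis is testable as a round trip with known ground truth.

## Worked example

Free inflation of the default 23 mm balloon (40 mm cylindrical region,
75 mm total, 0.09 mm membrane) with the shipped third-order Ogden
coefficients:

```python
import balloonmech as bm

design = bm.BalloonDesign()                 # 23 / 40 / 75 / 0.09 mm
material = bm.BALLOON_MEMBRANE_OGDEN        # third-order Ogden triplets
result = bm.solve_free_inflation(
    design, material,
    volume_targets_ml=[23.5, 24.0, 25.0, 26.0],
    n_elements=120,
)
for s in result.states:
    print(f"V = {s.volume_ml:6.2f} ml   P = {s.pressure_mmhg:7.1f} mmHg"
          f"   d = {s.central_diameter_mm():6.2f} mm")
```

prints

```
V =  23.50 ml   P =   562.6 mmHg   d =  23.24 mm
V =  24.00 ml   P =  1213.9 mmHg   d =  23.54 mm
V =  25.00 ml   P =  2382.0 mmHg   d =  24.23 mm
V =  26.00 ml   P =  3360.1 mmHg   d =  25.00 mm
```

i.e. the stress-free balloon holds ~23.06 ml at zero pressure, and
injecting ~3 ml raises the pressure to ~3360 mmHg (≈4.4 atm) while the
central diameter grows by only 2 mm — the signature stiffness of a
non-compliant balloon.  Inside a 22 mm bore the diameter is capped by
contact instead:

```python
phantom = bm.CylinderPhantom(inner_diameter_mm=22.0, thickness_mm=1.2,
                             length_mm=75.0, end_band_mm=10.6)
wall = bm.LinearElasticModel(young_modulus=13.19, poisson=0.25)  # stiff blend
constrained = bm.solve_constrained_inflation(
    design, material, phantom, wall, volume_targets_ml=[24.0, 25.0],
    n_elements=100)
print(constrained.contact_report["max_diameter_mm"])   # 23.94: the wall dilates
```

The command line mirrors the library:

```bash
balloonmech workflow --mode free --seed 1 --out runs/free
balloonmech simulate --config run.yaml --mode constrained --out curve.csv
balloonmech validate --exp exp.csv --comp comp.csv --out report.json
```

`workflow` generates a noisy synthetic bench experiment, runs the
forward model, and reports RMSE_P / RMSE_d at equal volume together with
CSV curves and a P–V / d–V figure.

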