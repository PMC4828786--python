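# Inflation of the balloon inside the 22 mm T50 implantation-site phantom.
schema_version: 1
design:
  nominal_diameter_mm: 23.0
  cylinder_length_mm: 40.0
  total_length_mm: 75.0
  thickness_mm: 0.09
  shaft_radius_mm: 3.0
  head_exponent: 1.0
material:
  type: ogden
  N: 3
  mu: [-4715.57, 2480.94, 2479.35]
  alpha: [4.89, 6.90, 1.13]
  delta: [1.38, 0.0, 0.0]
  units: MPa
  poisson: 0.45
phantom:
  inner_diameter_mm: 22.0
  thickness_mm: 1.2
  length_mm: 75.0
  end_band_mm: 10.6
  label: T50
  material:
    type: linear
    young_modulus_mpa: 13.19
    poisson: 0.25
protocol:
  flow_rate_ml_h: 40.0
  sampling_interval_s: 15.0
  initial_volume_ml: null
  injected_volume_ml: 2.5
solver:
  n_elements: 120
  max_step_ml: 0.25
noise:
  pressure_std_mmhg: 10.0
  pressure_quantum_mmhg: 152.0
  diameter_quantum_mm: 0.5
  seed: 0
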