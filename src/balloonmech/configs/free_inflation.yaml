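# Free inflation of the 23 mm non-compliant valvuloplasty balloon.
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
protocol:
  flow_rate_ml_h: 40.0
  sampling_interval_s: 15.0
  initial_volume_ml: null     # null = stress-free reference cavity volume
  injected_volume_ml: 2.5
solver:
  n_elements: 120
  max_step_ml: 0.25
noise:
  pressure_std_mmhg: 10.0
  pressure_quantum_mmhg: 152.0   # 0.2 atm manometer resolution
  diameter_quantum_mm: 0.5       # fluoroscopy pixel size
  seed: 0
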