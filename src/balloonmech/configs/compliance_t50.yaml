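# Compliance test of the T50 cylinder used to derive D of the phantom material.
schema_version: 1
phantom:
  inner_diameter_mm: 14.6
  thickness_mm: 1.2
  length_mm: 60.0
  end_band_mm: 0.0     # analysis formulas assume a uniform free cylinder
  label: T50
  material:
    type: linear
    young_modulus_mpa: 13.19
    poisson: 0.25
noise:
  volume_std_ml: 0.0
  seed: 0
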