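# Rapid-prototyped TangoPlus/VeroWhite composite cylinders: bench compliance /
# tensile characterisation summary used as a fixture.  T100..T75 were tested as
# d = 20 mm, l = 60 mm, t = 0.8 mm cylinders; the T50 implantation-site material
# was tested at t = 1.2 mm.  Rows with source=interpolated are synthetic
# interpolants consistent with the measured monotone trend (only the series
# endpoints were measured); treat them as qualitative placeholders.
name,tango_pct,vero_pct,thickness_mm,distensibility_per_mmhg,young_modulus_mpa,source
T100,100,0,0.8,0.0060,0.55,measured
T92,92,8,0.8,0.0046,0.80,interpolated
T83,83,17,0.8,0.0034,1.15,interpolated
T75,75,25,0.8,0.0024,1.62,measured
T50,50,50,1.2,0.00025,13.19,measured
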