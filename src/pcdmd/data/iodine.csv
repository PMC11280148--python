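# Mass attenuation coefficient of iodine (Z=53). K edge at 33.2 keV
# (duplicate-energy rows delimit the edge; interpolation never crosses it).
# Columns: energy_keV, mass_atten_cm2_g
# Compiled from standard published anchors plus a calibrated
# photoelectric+Compton parameterization; the diagnostic band (15-140 keV)
# matches published values closely, the sub-10 keV region (L/M edge
# structure omitted) is approximate. Density used for LAC (pure): 4.93 g/cm^3.
energy_keV,mass_atten_cm2_g
2.0,14200.0
3.0,4666.0
5.0,1154.0
10.0,171.2
15.0,56.4
20.0,25.7
30.0,8.52
33.1999,6.49
33.2001,37.5
35.0,32.4
40.0,22.4
50.0,12.2
60.0,7.45
80.0,3.44
100.0,1.942
150.0,0.68
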