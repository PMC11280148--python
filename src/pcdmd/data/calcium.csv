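# Mass attenuation coefficient of calcium (Z=20). K edge at 4.0381 keV
# (duplicate-energy rows delimit the edge; interpolation never crosses it).
# Columns: energy_keV, mass_atten_cm2_g
# Compiled from standard published anchors plus a calibrated
# photoelectric+Compton parameterization; the diagnostic band (30-140 keV)
# matches published values closely, the sub-10 keV region is approximate.
# Density used for LAC (pure material): 1.55 g/cm^3.
energy_keV,mass_atten_cm2_g
1.0,7534.0
1.5,2523.0
2.0,1161.0
3.0,388.0
4.0380,174.0
4.0382,1530.0
5.0,806.0
6.0,466.0
8.0,197.0
10.0,101.0
15.0,30.1
20.0,12.8
30.0,3.94
40.0,1.77
50.0,1.00
60.0,0.651
80.0,0.365
100.0,0.256
150.0,0.163
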