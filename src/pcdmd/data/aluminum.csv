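# Mass attenuation coefficient of aluminum (Z=13). K edge at 1.5596 keV
# (duplicate-energy rows delimit the edge; interpolation never crosses it).
# Columns: energy_keV, mass_atten_cm2_g
# Compiled from standard published photon mass-attenuation tables.
# Density used for LAC: 2.699 g/cm^3.
energy_keV,mass_atten_cm2_g
1.0,1185.0
1.5,402.2
1.5596,362.1
1.5597,3957.0
2.0,2263.0
3.0,788.0
4.0,360.5
5.0,193.4
6.0,115.3
8.0,50.33
10.0,26.23
15.0,7.955
20.0,3.441
30.0,1.128
40.0,0.5685
50.0,0.3681
60.0,0.2778
80.0,0.2018
100.0,0.1704
150.0,0.1378
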