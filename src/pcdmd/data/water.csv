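# Mass attenuation coefficient of liquid water.
# Columns: energy_keV, mass_atten_cm2_g
# Compiled from standard published photon mass-attenuation tables; log-log
# interpolation between rows. Density used for LAC: 1.000 g/cm^3.
energy_keV,mass_atten_cm2_g
1.0,4078.0
1.5,1376.0
2.0,617.3
3.0,192.9
4.0,82.78
5.0,42.58
6.0,24.64
8.0,10.37
10.0,5.329
15.0,1.673
20.0,0.8096
30.0,0.3756
40.0,0.2683
50.0,0.2269
60.0,0.2059
80.0,0.1837
100.0,0.1707
150.0,0.1505
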