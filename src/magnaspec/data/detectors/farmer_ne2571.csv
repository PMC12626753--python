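# detector = farmer_ne2571 (NE 2571 Farmer-type graphite-walled ion chamber)
# relative response per unit water dose vs photon energy, normalized ~1 in
# the MV range; synthetic digitized approximation of published Farmer-type
# energy-response data (near-flat within ~0.5% over 0.1-10 MeV, mild
# over-response around 60-100 keV, falling response below ~50 keV)
energy_MeV,relative_response
0.010,0.920
0.015,0.940
0.020,0.952
0.030,0.970
0.040,0.985
0.050,0.996
0.060,1.002
0.080,1.005
0.100,1.004
0.150,1.003
0.200,1.003
0.300,1.002
0.400,1.001
0.500,1.001
0.662,1.000
0.800,1.000
1.000,1.000
1.250,1.000
1.500,0.999
2.000,0.999
3.000,0.999
4.000,0.998
5.000,0.998
6.000,0.998
8.000,0.998
10.000,0.998
12.000,0.998
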