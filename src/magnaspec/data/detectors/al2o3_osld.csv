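# detector = al2o3_osld (Al2O3:C optically stimulated luminescent dosimeter)
# relative response per unit water dose vs photon energy,
# normalized to 1 at 1.25 MeV (Co-60-like quality); synthetic
# curve from the mass energy-absorption coefficient ratio of
# the detector material to water (first-order cavity model),
# generated by scripts/generate_detector_fixtures.py
energy_MeV,relative_response
0.010,3.8211
0.015,3.8103
0.020,3.7801
0.030,3.6070
0.040,3.2284
0.050,2.7081
0.060,2.2048
0.080,1.5517
0.100,1.2650
0.150,1.0633
0.200,1.0227
0.300,1.0054
0.400,1.0020
0.500,1.0009
0.600,1.0004
0.800,1.0001
1.000,1.0000
1.250,1.0000
1.500,1.0005
2.000,1.0042
3.000,1.0204
4.000,1.0423
5.000,1.0660
6.000,1.0895
8.000,1.1334
10.000,1.1720
12.000,1.2056
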