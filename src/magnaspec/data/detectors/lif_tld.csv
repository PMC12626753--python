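# detector = lif_tld (LiF:Mg,Ti thermoluminescent dosimeter (TLD-100 type))
# relative response per unit water dose vs photon energy,
# normalized to 1 at 1.25 MeV (Co-60-like quality); synthetic
# curve from the mass energy-absorption coefficient ratio of
# the detector material to water (first-order cavity model),
# generated by scripts/generate_detector_fixtures.py
energy_MeV,relative_response
0.010,1.3953
0.015,1.3937
0.020,1.3895
0.030,1.3653
0.040,1.3122
0.050,1.2393
0.060,1.1688
0.080,1.0773
0.100,1.0371
0.150,1.0089
0.200,1.0032
0.300,1.0008
0.400,1.0003
0.500,1.0001
0.600,1.0001
0.800,1.0000
1.000,1.0000
1.250,1.0000
1.500,1.0001
2.000,1.0010
3.000,1.0046
4.000,1.0095
5.000,1.0149
6.000,1.0202
8.000,1.0301
10.000,1.0388
12.000,1.0464
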