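# medium = water
# density_g_cm3 = 1.0
# coherent (Rayleigh) scattering folded out of all columns
# generated by scripts/generate_physics_fixtures.py; partials
# from Klein-Nishina + anchored photoelectric/pair fits,
# muen/rho transcribed from standard reference tables
energy_MeV,mu_rho_total,mu_rho_compton,mu_rho_photoelectric,mu_rho_pair,muen_rho
0.010,4.914098e+00,2.140983e-01,4.700000e+00,0.000000e+00,4.909184e+00
0.015,1.443347e+00,2.102514e-01,1.233095e+00,0.000000e+00,1.374000e+00
0.020,6.837809e-01,2.065826e-01,4.771983e-01,0.000000e+00,5.503000e-01
0.030,3.249302e-01,1.997321e-01,1.251981e-01,0.000000e+00,1.557000e-01
0.040,2.419130e-01,1.934624e-01,4.845068e-02,0.000000e+00,6.950000e-02
0.050,2.109027e-01,1.877022e-01,2.320047e-02,0.000000e+00,4.220000e-02
0.060,1.951030e-01,1.823914e-01,1.271156e-02,0.000000e+00,3.190000e-02
0.080,1.778390e-01,1.729197e-01,4.919273e-03,0.000000e+00,2.620000e-02
0.100,1.670730e-01,1.647174e-01,2.355580e-03,0.000000e+00,2.560000e-02
0.150,1.489078e-01,1.482898e-01,6.180117e-04,0.000000e+00,2.770000e-02
0.200,1.361194e-01,1.358802e-01,2.391657e-04,0.000000e+00,2.970000e-02
0.300,1.182151e-01,1.181524e-01,6.274769e-05,0.000000e+00,3.190000e-02
0.400,1.058849e-01,1.058606e-01,2.428286e-05,0.000000e+00,3.280000e-02
0.500,9.667502e-02,9.666339e-02,1.162778e-05,0.000000e+00,3.300000e-02
0.600,8.942616e-02,8.941979e-02,6.370870e-06,0.000000e+00,3.290000e-02
0.800,7.854552e-02,7.854305e-02,2.465477e-06,0.000000e+00,3.210000e-02
1.000,7.060439e-02,7.060321e-02,1.180587e-06,0.000000e+00,3.090000e-02
1.250,6.313428e-02,6.311912e-02,5.653206e-07,1.459227e-05,2.960000e-02
1.500,5.744328e-02,5.735505e-02,3.097396e-07,8.792289e-05,2.830000e-02
2.000,4.930636e-02,4.892533e-02,1.198668e-07,3.809139e-04,2.600000e-02
3.000,3.965130e-02,3.847305e-02,3.144834e-08,1.178216e-03,2.270000e-02
4.000,3.405183e-02,3.208247e-02,1.217026e-08,1.969347e-03,2.050000e-02
5.000,3.037606e-02,2.770048e-02,5.827695e-09,2.675579e-03,1.900000e-02
6.000,2.777468e-02,2.447944e-02,3.192999e-09,3.295242e-03,1.800000e-02
8.000,2.434186e-02,2.001821e-02,1.235665e-09,4.323653e-03,1.650000e-02
10.000,2.219000e-02,1.704456e-02,5.916949e-10,5.145438e-03,1.570000e-02
12.000,2.072707e-02,1.490392e-02,3.241901e-10,5.823150e-03,1.520000e-02
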