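# medium = air
# density_g_cm3 = 0.001205
# coherent (Rayleigh) scattering folded out of all columns
# generated by scripts/generate_physics_fixtures.py; partials
# from Klein-Nishina + anchored photoelectric/pair fits,
# muen/rho transcribed from standard reference tables
energy_MeV,mu_rho_total,mu_rho_compton,mu_rho_photoelectric,mu_rho_pair,muen_rho
0.010,4.802538e+00,1.925377e-01,4.610000e+00,0.000000e+00,4.742000e+00
0.015,1.398561e+00,1.890782e-01,1.209483e+00,0.000000e+00,1.334000e+00
0.020,6.538392e-01,1.857788e-01,4.680604e-01,0.000000e+00,5.389000e-01
0.030,3.024189e-01,1.796182e-01,1.228007e-01,0.000000e+00,1.537000e-01
0.040,2.215027e-01,1.739798e-01,4.752290e-02,0.000000e+00,6.830000e-02
0.050,1.915560e-01,1.687998e-01,2.275621e-02,0.000000e+00,4.100000e-02
0.060,1.764920e-01,1.640238e-01,1.246814e-02,0.000000e+00,3.040000e-02
0.080,1.603310e-01,1.555060e-01,4.825074e-03,0.000000e+00,2.410000e-02
0.100,1.504402e-01,1.481297e-01,2.310473e-03,0.000000e+00,2.340000e-02
0.150,1.339625e-01,1.333563e-01,6.061774e-04,0.000000e+00,2.500000e-02
0.200,1.224310e-01,1.221965e-01,2.345859e-04,0.000000e+00,2.680000e-02
0.300,1.063155e-01,1.062539e-01,6.154613e-05,0.000000e+00,2.880000e-02
0.400,9.522379e-02,9.519997e-02,2.381787e-05,0.000000e+00,2.960000e-02
0.500,8.694037e-02,8.692896e-02,1.140512e-05,0.000000e+00,2.970000e-02
0.600,8.042107e-02,8.041482e-02,6.248874e-06,0.000000e+00,2.960000e-02
0.800,7.063584e-02,7.063342e-02,2.418265e-06,0.000000e+00,2.890000e-02
1.000,6.349431e-02,6.349315e-02,1.157980e-06,0.000000e+00,2.780000e-02
1.250,5.677783e-02,5.676275e-02,5.544953e-07,1.452552e-05,2.670000e-02
1.500,5.166697e-02,5.157914e-02,3.038084e-07,8.752068e-05,2.550000e-02
2.000,4.437762e-02,4.399833e-02,1.175715e-07,3.791714e-04,2.340000e-02
3.000,3.577150e-02,3.459864e-02,3.084614e-08,1.172826e-03,2.050000e-02
4.000,3.081197e-02,2.885162e-02,1.193721e-08,1.960338e-03,1.860000e-02
5.000,2.757426e-02,2.491092e-02,5.716101e-09,2.663339e-03,1.730000e-02
6.000,2.529442e-02,2.201425e-02,3.131856e-09,3.280168e-03,1.640000e-02
8.000,2.230616e-02,1.800229e-02,1.212004e-09,4.303874e-03,1.520000e-02
10.000,2.045000e-02,1.532810e-02,5.803646e-10,5.121900e-03,1.450000e-02
12.000,1.919954e-02,1.340303e-02,3.179822e-10,5.796512e-03,1.400000e-02
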