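# medium = pmma
# density_g_cm3 = 1.19
# coherent (Rayleigh) scattering folded out of all columns
# generated by scripts/generate_physics_fixtures.py; partials
# from Klein-Nishina + anchored photoelectric/pair fits,
# muen/rho transcribed from standard reference tables
energy_MeV,mu_rho_total,mu_rho_compton,mu_rho_photoelectric,mu_rho_pair,muen_rho
0.010,3.088035e+00,2.080351e-01,2.880000e+00,0.000000e+00,3.026000e+00
0.015,9.598961e-01,2.042972e-01,7.555989e-01,0.000000e+00,8.324000e-01
0.020,4.931431e-01,2.007322e-01,2.924109e-01,0.000000e+00,3.328000e-01
0.030,2.707928e-01,1.940757e-01,7.671713e-02,0.000000e+00,9.630000e-02
0.040,2.176725e-01,1.879835e-01,2.968893e-02,0.000000e+00,4.750000e-02
0.050,1.966030e-01,1.823866e-01,1.421646e-02,0.000000e+00,3.270000e-02
0.060,1.850154e-01,1.772262e-01,7.789209e-03,0.000000e+00,2.550000e-02
0.080,1.710370e-01,1.680227e-01,3.014363e-03,0.000000e+00,2.450000e-02
0.100,1.614961e-01,1.600527e-01,1.443419e-03,0.000000e+00,2.460000e-02
0.150,1.444689e-01,1.440902e-01,3.786965e-04,0.000000e+00,2.690000e-02
0.200,1.321786e-01,1.320321e-01,1.465526e-04,0.000000e+00,2.890000e-02
0.300,1.148448e-01,1.148064e-01,3.844965e-05,0.000000e+00,3.100000e-02
0.400,1.028775e-01,1.028627e-01,1.487971e-05,0.000000e+00,3.190000e-02
0.500,9.393303e-02,9.392591e-02,7.125108e-06,0.000000e+00,3.210000e-02
0.600,8.689135e-02,8.688744e-02,3.903852e-06,0.000000e+00,3.200000e-02
0.800,7.632025e-02,7.631873e-02,1.510760e-06,0.000000e+00,3.120000e-02
1.000,6.860447e-02,6.860374e-02,7.234233e-07,0.000000e+00,3.000000e-02
1.250,6.134426e-02,6.133161e-02,3.464092e-07,1.230279e-05,2.880000e-02
1.500,5.580509e-02,5.573077e-02,1.897979e-07,7.412807e-05,2.740000e-02
2.000,4.786100e-02,4.753977e-02,7.345029e-08,3.211498e-04,2.520000e-02
3.000,3.837688e-02,3.738350e-02,1.927047e-08,9.933579e-04,2.210000e-02
4.000,3.283427e-02,3.117390e-02,7.457522e-09,1.660363e-03,1.990000e-02
5.000,2.917180e-02,2.691601e-02,3.571013e-09,2.255789e-03,1.850000e-02
6.000,2.656442e-02,2.378619e-02,1.956561e-09,2.778229e-03,1.740000e-02
8.000,2.309659e-02,1.945130e-02,7.571737e-10,3.645286e-03,1.600000e-02
10.000,2.090000e-02,1.656186e-02,3.625705e-10,4.338135e-03,1.520000e-02
12.000,1.939136e-02,1.448184e-02,1.986527e-10,4.909517e-03,1.470000e-02
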