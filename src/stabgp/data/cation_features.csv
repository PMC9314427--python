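cation,symbol,charge,atomic_number,melting_point_k,molar_heat_capacity,ionic_radius_pm,polarizability_a3,electron_affinity_ev,electronegativity,unfilled_s,unfilled_p,unfilled_d,unfilled_f
Li+,Li,1,3,453.7,24.86,76.0,24.33,0.618,0.98,2,6,10,14
Na+,Na,1,11,371.0,28.23,102.0,24.11,0.548,0.93,2,6,10,14
K+,K,1,19,336.5,29.60,138.0,43.06,0.501,0.82,2,6,10,14
Rb+,Rb,1,37,312.5,31.06,152.0,47.24,0.486,0.82,2,6,10,14
Cs+,Cs,1,55,301.6,32.21,167.0,59.42,0.472,0.79,2,6,10,14
Cu+,Cu,1,29,1357.8,24.44,77.0,6.20,1.236,1.90,2,6,0,14
Ag+,Ag,1,47,1234.9,25.35,115.0,7.20,1.302,1.93,2,6,0,14
Tl+,Tl,1,81,577.0,26.32,150.0,7.60,0.377,1.62,0,6,0,0
Mg2+,Mg,2,12,923.0,24.87,72.0,10.60,0.000,1.31,2,6,10,14
Ca2+,Ca,2,20,1115.0,25.93,100.0,22.80,0.025,1.00,2,6,10,14
Sr2+,Sr,2,38,1050.0,26.40,118.0,27.60,0.048,0.95,2,6,10,14
Ba2+,Ba,2,56,1000.0,28.07,135.0,39.70,0.145,0.89,2,6,10,14
Mn2+,Mn,2,25,1519.0,26.32,83.0,9.40,0.000,1.55,2,6,5,14
Fe2+,Fe,2,26,1811.0,25.10,78.0,8.40,0.151,1.83,2,6,4,14
Co2+,Co,2,27,1768.0,24.81,74.5,7.50,0.662,1.88,2,6,3,14
Ni2+,Ni,2,28,1728.0,26.07,69.0,6.80,1.156,1.91,2,6,2,14
Cu2+,Cu,2,29,1357.8,24.44,73.0,6.20,1.236,1.90,2,6,1,14
Zn2+,Zn,2,30,692.7,25.39,74.0,5.75,0.000,1.65,2,6,0,14
Pd2+,Pd,2,46,1828.0,25.98,86.0,4.80,0.562,2.20,2,6,2,14
Cd2+,Cd,2,48,594.2,26.02,95.0,7.36,0.000,1.69,2,6,0,14
Sn2+,Sn,2,50,505.1,27.11,118.0,7.70,1.112,1.96,0,6,0,14
Hg2+,Hg,2,80,234.3,27.98,102.0,5.02,0.000,2.00,2,6,0,0
Pb2+,Pb,2,82,600.6,26.65,119.0,7.01,0.356,1.87,0,6,0,0
Al3+,Al,3,13,933.5,24.20,53.5,6.80,0.432,1.61,2,6,10,14
Sc3+,Sc,3,21,1814.0,25.52,74.5,17.80,0.188,1.36,2,6,10,14
Cr3+,Cr,3,24,2180.0,23.35,61.5,11.60,0.676,1.66,2,6,7,14
Fe3+,Fe,3,26,1811.0,25.10,64.5,8.40,0.151,1.83,2,6,5,14
Ga3+,Ga,3,31,302.9,25.86,62.0,8.12,0.430,1.81,2,6,0,14
Y3+,Y,3,39,1799.0,26.53,90.0,22.70,0.307,1.22,2,6,10,14
In3+,In,3,49,429.8,26.74,80.0,10.20,0.300,1.78,2,6,0,14
La3+,La,3,57,1193.0,27.11,103.2,31.10,0.470,1.10,2,6,10,14
Ce3+,Ce,3,58,1068.0,26.94,101.0,29.60,0.500,1.12,2,6,10,13
Nd3+,Nd,3,60,1297.0,27.45,98.3,31.40,0.090,1.14,2,6,10,11
Eu3+,Eu,3,63,1099.0,27.66,94.7,27.70,0.110,1.20,2,6,10,8
Gd3+,Gd,3,64,1585.0,37.03,93.8,23.50,0.130,1.20,2,6,10,7
Lu3+,Lu,3,71,1925.0,26.86,86.1,21.90,0.340,1.27,2,6,10,0
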