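metabolite,window_hi_ppm,window_lo_ppm
Isoleucine,0.980,0.900
Leucine,1.750,1.670
Valine,1.090,1.010
3-Hydroxybutyrate,1.240,1.160
2-Hydroxyisobutyrate,1.480,1.400
Lactate,1.370,1.290
Alanine,1.600,1.520
Lysine,1.940,1.860
4-Aminobutyrate,2.330,2.250
N-acetyl aspartate,2.050,1.970
Glutamate,2.160,2.080
Succinate,2.450,2.370
Glutamine,2.560,2.480
Aspartate,2.720,2.640
Trimethylamine,2.930,2.850
Creatine,3.070,2.990
Creatine,3.970,3.890
Choline,3.240,3.160
Phosphocholine,3.360,3.280
Taurine,3.470,3.390
Glycine,3.600,3.520
Myo-inositol,3.710,3.630
Threonine,4.290,4.210
Ascorbate,4.560,4.480
Uracil,5.840,5.760
Uridine,5.960,5.880
Adenosine,6.120,6.040
Adenosine,8.300,8.220
Inosine,6.240,6.160
Fumarate,6.560,6.480
Tyrosine,6.940,6.860
Tyrosine,7.230,7.150
Histidine,7.740,7.660
Histidine,7.130,7.050
Phenylalanine,7.410,7.330
Xanthine,7.940,7.860
Oxypurinol,8.160,8.080
ATP,8.390,8.310
Formate,8.500,8.420
ADP,8.610,8.530
AMP,8.720,8.640
Niacinamide,8.980,8.900
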