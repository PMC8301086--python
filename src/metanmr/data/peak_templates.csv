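metabolite,center_ppm,weight,hwhm_ppm
Isoleucine,0.94,1.0,0.003
Leucine,1.71,1.0,0.003
Valine,1.05,1.0,0.003
3-Hydroxybutyrate,1.20,1.0,0.003
2-Hydroxyisobutyrate,1.44,1.0,0.003
Lactate,1.33,1.0,0.003
Alanine,1.56,1.0,0.003
Lysine,1.90,1.0,0.003
4-Aminobutyrate,2.29,1.0,0.003
N-acetyl aspartate,2.01,1.0,0.003
Glutamate,2.12,1.0,0.003
Succinate,2.41,1.0,0.003
Glutamine,2.52,1.0,0.003
Aspartate,2.68,1.0,0.003
Trimethylamine,2.89,1.0,0.003
Creatine,3.03,0.65,0.003
Creatine,3.93,0.35,0.003
Choline,3.20,1.0,0.003
Phosphocholine,3.32,1.0,0.003
Taurine,3.43,1.0,0.003
Glycine,3.56,1.0,0.003
Myo-inositol,3.67,1.0,0.003
Threonine,4.25,1.0,0.003
Ascorbate,4.52,1.0,0.003
Uracil,5.80,1.0,0.003
Uridine,5.92,1.0,0.003
Adenosine,6.08,0.70,0.003
Adenosine,8.26,0.30,0.003
Inosine,6.20,1.0,0.003
Fumarate,6.52,1.0,0.003
Tyrosine,6.90,0.60,0.003
Tyrosine,7.19,0.40,0.003
Histidine,7.70,0.65,0.003
Histidine,7.09,0.35,0.003
Phenylalanine,7.37,1.0,0.003
Xanthine,7.90,1.0,0.003
Oxypurinol,8.12,1.0,0.003
ATP,8.35,1.0,0.003
Formate,8.46,1.0,0.003
ADP,8.57,1.0,0.003
AMP,8.68,1.0,0.003
Niacinamide,8.94,1.0,0.003
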