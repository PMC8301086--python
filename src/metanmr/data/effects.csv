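metabolite,model_vs_sham,TH_vs_model,TM_vs_model,TL_vs_model
Isoleucine,0.41,-0.12,-0.18,-0.28
Leucine,0.3,-0.34,-0.29,-0.43
Valine,0.2,-0.11,-0.22,-0.39
3-Hydroxybutyrate,0.24,-0.1,0.02,-0.37
2-Hydroxyisobutyrate,0.78,0.22,0.28,0.09
Lactate,0.24,-0.14,-0.28,-0.29
Alanine,0.63,0.39,0.31,0.12
Lysine,0.05,-0.09,-0.03,-0.24
4-Aminobutyrate,-0.18,0.25,0.19,0.22
N-acetyl aspartate,-0.37,0.14,-0.13,0.04
Glutamate,0.07,-0.05,0.09,0.01
Succinate,0.15,0.09,-0.04,0.39
Glutamine,0.11,-0.12,-0.03,-0.11
Aspartate,-0.18,0.14,0.07,-0.06
Trimethylamine,-0.09,-0.32,-0.28,-0.28
Creatine,-0.18,0.05,-0.1,-0.14
Choline,0.19,-0.06,-0.05,-0.12
Phosphocholine,-0.01,0.09,0.16,-0.07
Taurine,0.0,0.02,0.13,0.09
Glycine,0.48,0.21,0.3,0.18
Myo-inositol,0.04,0.01,0.05,0.1
Threonine,0.52,0.21,0.17,0.21
Ascorbate,-0.2,0.15,0.44,0.01
Uracil,0.22,0.19,0.13,0.2
Uridine,-0.02,0.08,-0.15,-0.09
Adenosine,-0.5,0.17,0.1,0.05
Inosine,0.06,-0.29,-0.47,-0.37
Fumarate,0.67,0.24,0.29,0.09
Tyrosine,-0.1,-0.06,0.03,0.02
Histidine,0.01,0.09,-0.05,0.97
Phenylalanine,0.25,-0.07,-0.13,-0.05
Xanthine,-0.29,-0.06,-0.08,-0.19
Oxypurinol,0.38,0.09,0.33,0.27
ATP,-0.21,1.33,1.34,0.97
Formate,0.4,0.73,0.82,0.92
ADP,0.09,0.27,0.39,0.01
AMP,-0.38,0.2,0.56,0.52
Niacinamide,-0.09,0.05,-0.13,0.05
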