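metabolite,baseline_mean
Isoleucine,0.5
Leucine,0.9
Valine,0.7
3-Hydroxybutyrate,0.6
2-Hydroxyisobutyrate,0.3
Lactate,8.0
Alanine,2.0
Lysine,1.2
4-Aminobutyrate,2.5
N-acetyl aspartate,6.0
Glutamate,10.0
Succinate,0.8
Glutamine,4.0
Aspartate,2.5
Trimethylamine,0.2
Creatine,7.0
Choline,1.5
Phosphocholine,1.8
Taurine,5.0
Glycine,1.3
Myo-inositol,5.5
Threonine,0.9
Ascorbate,1.8
Uracil,0.3
Uridine,0.35
Adenosine,0.4
Inosine,0.7
Fumarate,0.15
Tyrosine,0.45
Histidine,0.35
Phenylalanine,0.4
Xanthine,0.25
Oxypurinol,0.2
ATP,2.5
Formate,0.15
ADP,0.8
AMP,1.0
Niacinamide,0.3
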