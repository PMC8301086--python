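from,to
AMP,ADP
ADP,ATP
AMP,Adenosine
Adenosine,Inosine
Inosine,Xanthine
Glutamate,Glutamine
Glutamate,4-Aminobutyrate
Aspartate,N-acetyl aspartate
Succinate,Fumarate
Choline,Phosphocholine
Phenylalanine,Tyrosine
Uridine,Uracil
Threonine,Glycine
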