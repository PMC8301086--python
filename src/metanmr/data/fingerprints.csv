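metabolite,bits
"Isoleucine",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000011000100000000000000000011000000010000000100000001000000000101001111111100100
"Leucine",0000000000000000000000000000000000000000000000000000010000000000000000000100000000010000010000100000000100000010001000000010000000100000001000000000101001111111100100
"Valine",0000000000000000000000000000000000000000000000000000010000000000000000000100000000010000000000100000000000000000000000000010000000100000001000000000101001011111100100
"3-Hydroxybutyrate",0000000000000000000000000000000000000000000000000000100000000000000000000000000000000000100000000000000100000000001000000010000000110000001000000100000101101011000100
"2-Hydroxyisobutyrate",0000000000000000000000000000000000000000000000000000010000000000010000010100000000000000000000000000000000000001000000000010000000100000001000000100100101001011000100
"Lactate",0000000000000000000000000000000000000000000000000000010000000000000000010000000000000000000000000000000000000000000000000010000000100000001000000100000101001011000100
"Alanine",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000000000100000000000000000000000000010000000100000001000000000001001011111100100
"Lysine",0000000000000000000000000000000000000000000000000000010000000000000000000000000001010000011000100001000100000010000001000010000010100000001001000010001011111110100100
"4-Aminobutyrate",0000000000000000000000000000000000000000000000000000000000000000000000000000000001010000011000000001000100000010000001000010000000110000001000000010001011101110100100
"N-acetyl aspartate",0000000000000000000000000000000000000000000000000000110000000000000000000000000000000000010100101000000100010110000010000010000000110001001100000100001001111111100100
"Glutamate",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000011000100000000100000010000001000010000000110001001100000110001001111110100100
"Succinate",0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000010000000000000100000000000001000010000000110001001100000110000001101010000100
"Glutamine",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000011100100000000100000110000011000010000000110001001001000110001001111110100100
"Aspartate",0000000000000000000000000000000000000000000000000000110000000000000000000000000000010000010000101000000100000010000000000010000000110001001100000100001001111110100100
"Trimethylamine",0000000000000000000000000000000000000000000000000000000000000000000000000100000000001100000010000000000000000000000000000100000000000000000010000001100000000101100000
"Creatine",0000000000000000000000001000000000000000001000000000000000000000000000000000110000011100010010100001000101000000001000100110000000110000001001000001001011111111100100
"Choline",0000000000000000000000000000010000000000000000001000000000000000000000000100000001001100000010100001000100001011001101000100000000010000011010000011100010101101100100
"Phosphocholine",0000000000000000000000000000110000000000001000011000000000000000000010000100000000001100011010100001010001001011001101000101010001110000011110000111100010101111100100
"Taurine",0000000000000000000000000000000000000011000000010010101001011000001010001000000001010001010000001001010101000011000001000001000001110001011000000111001010100110100100
"Myo-inositol",0000000000000000000000000000000000000000000000000000110000000000000000010000000000000000100000000000000000000000000000000000001000100000001100100100010100001010001110
"Glycine",0000000000000000000000000000000000000000000000000000010000000000000000000000000001010000000000100001000100000000000000000010000000110000001000000000001011101110100100
"Threonine",0000000000000000000000000000000000000000000000000000110000000000000000000000000000010000100000100000000000000000000000000010000000100000001000000100001101011111100100
"Ascorbate",0000000000000000000000000000000000000000000000000000110010000000000000010001000001100000101000010010000100001000000000000010001000110000101100100100010111101010000110
"Adenosine",0000000000000000000000000000000000000100000000000000110010000100100000010010101101111000111100111100100010001100000010011100101000111010101101100101011110111110111110
"Inosine",0000000000000000000000000000000000000100000000000000110010000100100000010010101101101000111100111100100010001100100010011100101000111000101101100101011111111110111110
"Uridine",0000000000000000000000000000000000001000000000000000110010000100100000010010100101101000111100111100000001001100100010011100001000111001101101110101011111111110111110
"Uracil",0000000000000000000000000000000000001000001000000000100000000000100000000000100100000000100100001100000001000100100010011000001000100001100001100000001001010010111110
"AMP",0000000000000000000000000000100000000100001000010000010010000100100010010010101100111000111100111100110011001101000010011101111001111010101101100101011110111110111110
"ADP",0000000000000000000000000000100000000100001000010000110010000100100010010010101100111000111100111100110011001101000010011101111001111011101101100101011110111110111110
"ATP",0000000000000000000000000000100000000100001000010000110010000100100010010010101100111000111100111100110011001101000010011101111001111011101101100101011110111110111110
"Fumarate",0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000010000000000000000000000010000000100001001100000100000001001010000100
"Tyrosine",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000010000100000000100000010100000000010001000100000001000100100001101111110111110
"Phenylalanine",0000000000000000000000000000000000000000000000000000010000000000000000000000000000010000010000100000000100000010000000000010000000100000001000000000001001111110111110
"Niacinamide",0000000000000000000000000000000000000000000000000000000000000000100000000000000100010000000100001100000000000100000010001000000000000000100001000000001001010100111110
"Histidine",0000000000000000000000000000000000000000000000000000010000000000100000000000101100110000011000110000000100000010000000011010000000100000101001000000001001111110110110
"Xanthine",0000000000000000000000000000000000001100001000000000100000000000100000000000101100100000100100111100100011000100100010011000101000100001100001100000001001010010111110
"Oxypurinol",0000000000000000000000000000000000001100001000000001100000000000100010000000101100100000100101011100100011000100100010011001101000100001100001100000001001010010111110
"Formate",0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000010000000000000001000000000000001001010000100
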