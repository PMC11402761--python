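parameter,unit,standard,raw_weight,relative_weight
EC,uS/cm,300,,0.0009
Na,mg/l,200,,0.0012
K,mg/l,12,,0.0230
TH,mg/l,35,,0.0079
Fe,mg/l,0.3,,0.920
TDS,mg/l,500,,0.0006
pH,,8.5,,0.0345
Cl,mg/l,200,,0.0014
HCO3,mg/l,240,,0.0012
Mg,mg/l,30,,0.0092
Ca,mg/l,75,,0.0037
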