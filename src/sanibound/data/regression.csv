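# stepwise general linear model for GWQI; r_squared=0.796
term,coefficient,se,t,p
intercept,157.022,12.815,12.253,0.000
depth_m,-2.332,0.348,-6.709,0.000
dist_latrine_m,-0.399,0.090,-4.442,0.000
transmissivity_m2day,3.873,1.951,1.985,0.050
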