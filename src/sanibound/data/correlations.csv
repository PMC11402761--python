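variable,gwqi_actual,elevation_m,dist_latrine_m,depth_m,transmissivity_m2day,age_yr
gwqi_actual,1,0.017,-0.753,-0.855,0.671,0.090
elevation_m,0.017,1,-0.021,0.062,-0.065,-0.020
dist_latrine_m,-0.753,-0.021,1,0.688,-0.464,-0.145
depth_m,-0.855,0.062,0.688,1,-0.626,-0.047
transmissivity_m2day,0.671,-0.065,-0.464,-0.626,1,0.037
age_yr,0.090,-0.020,-0.145,-0.047,0.037,1
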