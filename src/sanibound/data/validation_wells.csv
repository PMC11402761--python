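no,lon,lat,gwqi_actual,elevation_m,dist_latrine_m,depth_m,transmissivity_m2day,age_yr,gwqi_predicted
01,11.472710,3.768865,172.124,575.000,27.000,19.000,7.903,19,132.738
11,11.478943,3.749364,143.009,702.000,50.000,12.590,5.909,16,130.723
15,11.579444,3.859722,59.761,698.000,76.000,31.010,2.249,23,63.405
16,11.584204,3.861545,2.758,711.000,111.000,39.480,3.186,22,33.400
21,11.455501,3.890899,20.816,732.000,105.000,28.000,1.874,19,57.370
22,11.568570,3.889760,9.559,696.000,129.000,43.280,0.521,18,7.071
26,11.458870,3.860100,140.914,753.000,40.000,11.580,0.328,15,115.443
27,11.474290,3.915780,76.142,854.000,84.000,35.220,3.661,13,55.904
38,11.535167,3.957377,33.346,679.000,90.000,35.860,2.457,13,47.362
49,11.552083,3.878250,93.458,749.000,69.000,34.100,1.717,16,56.961
51,11.550278,3.816457,79.050,698.000,63.000,38.220,3.422,9,56.392
53,11.507167,3.770233,139.696,712.000,3.000,10.730,4.838,11,149.649
54,11.518417,3.773733,184.465,707.000,22.000,4.280,6.657,11,164.090
55,11.538644,3.882864,16.123,703.000,83.000,23.290,1.440,12,75.401
56,11.529806,3.785278,121.251,706.000,7.000,11.060,2.264,12,137.316
57,11.490556,3.794444,137.932,674.000,12.000,12.000,2.608,13,134.471
65,11.518417,3.773733,163.701,685.000,10.000,17.970,6.484,15,136.418
70,11.494817,3.878350,180.775,736.000,8.000,4.540,5.302,17,163.824
73,11.452600,3.897300,8.542,761.000,116.000,48.480,0.750,17,1.074
78,11.496758,3.863361,156.580,753.000,10.000,9.000,1.841,19,139.263
90,11.529806,3.785278,10.361,705.000,21.000,37.050,0.655,24,65.149
91,11.540843,3.833605,196.235,754.000,8.000,3.990,5.728,24,166.751
95,11.539992,3.907944,139.107,755.000,95.000,12.860,6.070,26,112.767
99,11.486053,3.767282,151.658,696.000,11.000,8.320,2.946,27,144.725
101,11.527756,3.906179,68.773,750.000,62.000,50.310,5.331,29,36.111
108,11.454750,3.865510,84.815,711.000,58.000,27.220,2.045,33,78.597
109,11.573167,3.862056,160.130,638.000,25.000,15.330,6.875,33,138.078
110,11.480087,3.942989,145.460,924.000,8.000,17.730,4.184,40,128.864
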