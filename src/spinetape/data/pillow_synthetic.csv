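strain,stress_kPa
0.0,0.0
0.025,1.662429
0.05,2.885088
0.075,3.78601
0.1,4.451554
0.125,4.944929
0.15,5.312416
0.175,5.587946
0.2,5.796446
0.225,5.956304
0.25,6.081176
0.275,6.181332
0.3,6.264641
0.325,6.337315
0.35,6.404465
0.375,6.470522
0.4,6.539571
0.425,6.615602
0.45,6.702724
0.475,6.805336
0.5,6.928276
0.525,7.076952
0.55,7.257466
0.575,7.476721
0.6,7.742537
0.625,8.063752
0.65,8.450332
0.675,8.913477
0.7,9.465731
0.725,10.121091
0.75,10.895126
0.775,11.805088
0.8,12.870037
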