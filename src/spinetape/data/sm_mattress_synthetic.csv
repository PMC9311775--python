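strain,stress_kPa
0.0,0.0
0.025,0.753936
0.05,1.30843
0.075,1.717011
0.1,2.018845
0.125,2.242598
0.15,2.409259
0.175,2.534216
0.2,2.628774
0.225,2.701271
0.25,2.757903
0.275,2.803325
0.3,2.841107
0.325,2.874066
0.35,2.904519
0.375,2.934477
0.4,2.965792
0.425,3.000273
0.45,3.039784
0.475,3.08632
0.5,3.142075
0.525,3.209502
0.55,3.291368
0.575,3.390803
0.6,3.511355
0.625,3.657031
0.65,3.83235
0.675,4.042393
0.7,4.292848
0.725,4.590064
0.75,4.9411
0.775,5.353781
0.8,5.836752
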