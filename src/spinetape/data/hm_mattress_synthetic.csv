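strain,stress_kPa
0.0,0.0
0.025,4.523615
0.05,7.850581
0.075,10.302067
0.1,12.113073
0.125,13.455588
0.15,14.455554
0.175,15.205296
0.2,15.772643
0.225,16.207629
0.25,16.547418
0.275,16.819951
0.3,17.046642
0.325,17.244395
0.35,17.427115
0.375,17.606864
0.4,17.794752
0.425,18.001639
0.45,18.238706
0.475,18.517921
0.5,18.852451
0.525,19.257012
0.55,19.748206
0.575,20.34482
0.6,21.068129
0.625,21.942183
0.65,22.994102
0.675,24.25436
0.7,25.757091
0.725,27.540384
0.75,29.646601
0.775,32.122688
0.8,35.02051
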