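strain,stress_kPa
0.0,0.0
0.025,1.583265
0.05,2.747703
0.075,3.605723
0.1,4.239576
0.125,4.709456
0.15,5.059444
0.175,5.321854
0.2,5.520425
0.225,5.67267
0.25,5.791596
0.275,5.886983
0.3,5.966325
0.325,6.035538
0.35,6.09949
0.375,6.162402
0.4,6.228163
0.425,6.300574
0.45,6.383547
0.475,6.481273
0.5,6.598358
0.525,6.739954
0.55,6.911872
0.575,7.120687
0.6,7.373845
0.625,7.679764
0.65,8.047936
0.675,8.489026
0.7,9.014982
0.725,9.639135
0.75,10.37631
0.775,11.242941
0.8,12.257178
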