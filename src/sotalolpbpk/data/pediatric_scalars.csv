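sex,age_y,co_per_kg_l_h,hematocrit,blood_frac
male,0.0,12.9,0.5,0.08
male,0.25,11.6,0.4325,0.079
male,0.5,10.8,0.365,0.078
male,1.0,10.0,0.37,0.077
male,1.5,9.3,0.3725,0.07675
male,2.0,8.6,0.375,0.0765
male,3.0,8.1,0.37833333333333335,0.0764
male,4.0,7.7,0.38166666666666665,0.0763
male,5.0,7.4,0.385,0.0762
male,6.0,7.150000000000001,0.388,0.07616
male,7.0,6.949999999999999,0.391,0.07612000000000001
male,8.0,6.800000000000001,0.394,0.07608
male,9.0,6.6499999999999995,0.397,0.07604
male,10.0,6.500000000000001,0.4,0.076
male,11.0,6.38,0.404,0.07596
male,12.0,6.260000000000001,0.40800000000000003,0.07592
male,13.0,6.14,0.412,0.07588
male,14.0,6.0200000000000005,0.416,0.07584
male,15.0,5.9,0.42,0.0758
male,16.0,5.79,0.43,0.07577142857142857
male,17.0,5.68,0.44,0.07574285714285714
male,18.0,5.571428571428571,0.45,0.0757142857142857
female,0.0,13.660769230769233,0.5,0.08
female,0.25,12.284102564102565,0.4325,0.079
female,0.5,11.436923076923078,0.365,0.078
female,1.0,10.58974358974359,0.37,0.077
female,1.5,9.84846153846154,0.3725,0.07675
female,2.0,9.107179487179488,0.375,0.0765
female,3.0,8.577692307692308,0.37833333333333335,0.0764
female,4.0,8.154102564102566,0.38166666666666665,0.0763
female,5.0,7.836410256410257,0.385,0.0762
female,6.0,7.571666666666667,0.388,0.07616
female,7.0,7.359871794871796,0.391,0.07612000000000001
female,8.0,7.201025641025642,0.394,0.07608
female,9.0,7.042179487179489,0.397,0.07604
female,10.0,6.883333333333334,0.4,0.076
female,11.0,6.7562564102564115,0.404,0.07596
female,12.0,6.629179487179487,0.40800000000000003,0.07592
female,13.0,6.5021025641025645,0.412,0.07588
female,14.0,6.375025641025641,0.416,0.07584
female,15.0,6.247948717948718,0.42,0.0758
female,16.0,6.131461538461539,0.41333333333333333,0.07331111111111112
female,17.0,6.014974358974359,0.4066666666666667,0.07082222222222222
female,18.0,5.9,0.4,0.06833333333333333
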