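sex,organ,volume_frac,flow_frac
male,adipose,0.23142857142857143,0.05
male,bone,0.14285714285714285,0.05
male,brain,0.020714285714285713,0.12
male,gut,0.016428571428571428,0.15
male,heart,0.004714285714285714,0.04
male,kidney,0.004428571428571428,0.19
male,liver,0.025714285714285714,0.065
male,lung,0.007571428571428572,1.0
male,muscle,0.40285714285714286,0.17
male,skin,0.04714285714285714,0.05
male,spleen,0.002142857142857143,0.03
male,pancreas,0.002,0.01
female,adipose,0.31666666666666665,0.05
female,bone,0.12666666666666665,0.05
female,brain,0.021666666666666667,0.12
female,gut,0.016666666666666666,0.15
female,heart,0.004166666666666667,0.04
female,kidney,0.004666666666666667,0.19
female,liver,0.02333333333333333,0.065
female,lung,0.007,1.0
female,muscle,0.2916666666666667,0.17
female,skin,0.03833333333333333,0.05
female,spleen,0.0021666666666666666,0.03
female,pancreas,0.002,0.01
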