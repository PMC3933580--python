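sex,organ,age_y,volume_frac,flow_frac
male,adipose,0.0,0.15,0.03
male,adipose,0.5,0.23,0.033
male,adipose,1.0,0.23,0.035
male,adipose,2.0,0.2,0.038
male,adipose,5.0,0.15,0.042
male,adipose,10.0,0.15,0.046
male,adipose,15.0,0.18,0.049
male,adipose,18.0,0.23142857142857143,0.05
male,bone,0.0,0.08,0.03
male,bone,0.5,0.085,0.033
male,bone,1.0,0.09,0.035
male,bone,2.0,0.1,0.038
male,bone,5.0,0.11,0.042
male,bone,10.0,0.12,0.046
male,bone,15.0,0.135,0.049
male,bone,18.0,0.14285714285714285,0.05
male,brain,0.0,0.109,0.15
male,brain,0.5,0.088,0.25
male,brain,1.0,0.095,0.27
male,brain,2.0,0.081,0.26
male,brain,5.0,0.066,0.23
male,brain,10.0,0.042,0.18
male,brain,15.0,0.025,0.13
male,brain,18.0,0.020714285714285713,0.12
male,gut,0.0,0.012,0.14
male,gut,0.5,0.013,0.142
male,gut,1.0,0.0135,0.144
male,gut,2.0,0.014,0.146
male,gut,5.0,0.0145,0.148
male,gut,10.0,0.015,0.149
male,gut,15.0,0.0158,0.15
male,gut,18.0,0.016428571428571428,0.15
male,heart,0.0,0.0057,0.03
male,heart,0.5,0.0055,0.032
male,heart,1.0,0.005,0.033
male,heart,2.0,0.0048,0.035
male,heart,5.0,0.0045,0.037
male,heart,10.0,0.0044,0.039
male,heart,15.0,0.0044,0.04
male,heart,18.0,0.004714285714285714,0.04
male,liver,0.0,0.0371,0.06
male,liver,0.5,0.04,0.061
male,liver,1.0,0.033,0.062
male,liver,2.0,0.03,0.062
male,liver,5.0,0.029,0.063
male,liver,10.0,0.027,0.064
male,liver,15.0,0.0245,0.065
male,liver,18.0,0.025714285714285714,0.065
male,lung,0.0,0.0171,1.0
male,lung,0.5,0.0145,1.0
male,lung,1.0,0.013,1.0
male,lung,2.0,0.011,1.0
male,lung,5.0,0.0095,1.0
male,lung,10.0,0.0085,1.0
male,lung,15.0,0.0078,1.0
male,lung,18.0,0.007571428571428572,1.0
male,muscle,0.0,0.22,0.08
male,muscle,0.5,0.22,0.085
male,muscle,1.0,0.23,0.09
male,muscle,2.0,0.26,0.1
male,muscle,5.0,0.31,0.12
male,muscle,10.0,0.35,0.145
male,muscle,15.0,0.4,0.165
male,muscle,18.0,0.40285714285714286,0.17
male,skin,0.0,0.05,0.06
male,skin,0.5,0.048,0.058
male,skin,1.0,0.045,0.056
male,skin,2.0,0.043,0.054
male,skin,5.0,0.042,0.052
male,skin,10.0,0.044,0.051
male,skin,15.0,0.046,0.05
male,skin,18.0,0.04714285714285714,0.05
male,spleen,0.0,0.00286,0.03
male,spleen,0.5,0.0027,0.03
male,spleen,1.0,0.0026,0.03
male,spleen,2.0,0.0025,0.03
male,spleen,5.0,0.0024,0.03
male,spleen,10.0,0.0023,0.03
male,spleen,15.0,0.0022,0.03
male,spleen,18.0,0.002142857142857143,0.03
male,pancreas,0.0,0.00171,0.01
male,pancreas,0.5,0.0018,0.01
male,pancreas,1.0,0.00185,0.01
male,pancreas,2.0,0.0019,0.01
male,pancreas,5.0,0.00195,0.01
male,pancreas,10.0,0.00198,0.01
male,pancreas,15.0,0.002,0.01
male,pancreas,18.0,0.002,0.01
male,kidney,0.0,0.0071,
male,kidney,0.5,0.0068,
male,kidney,1.0,0.0065,
male,kidney,2.0,0.006,
male,kidney,5.0,0.0055,
male,kidney,10.0,0.005,
male,kidney,15.0,0.0046,
male,kidney,18.0,0.004428571428571428,
male,kidney,0.0,,0.06511627906976744
male,kidney,0.25,,0.07758620689655173
male,kidney,0.5,,0.08703703703703702
male,kidney,1.0,,0.099
male,kidney,1.5,,0.1096774193548387
male,kidney,2.0,,0.12093023255813955
male,kidney,3.0,,0.12853835978835979
male,kidney,4.0,,0.13536641929499071
male,kidney,5.0,,0.14101110038610037
male,kidney,6.0,,0.1461038961038961
male,kidney,7.0,,0.15047533401849947
male,kidney,8.0,,0.1539653361344538
male,kidney,9.0,,0.1576127819548872
male,kidney,10.0,,0.16142857142857145
male,kidney,11.0,,0.16464677563815494
male,kidney,12.0,,0.1679883614787768
male,kidney,13.0,,0.17146056305258262
male,kidney,14.0,,0.17507119126720455
male,kidney,15.0,,0.17882869249394673
male,kidney,16.0,,0.18242659758203797
male,kidney,17.0,,0.18616385814889339
male,kidney,18.0,,0.19
female,adipose,0.0,0.15,0.03
female,adipose,0.5,0.23,0.033
female,adipose,1.0,0.23,0.035
female,adipose,2.0,0.2,0.038
female,adipose,5.0,0.15,0.042
female,adipose,10.0,0.15,0.046
female,adipose,15.0,0.18,0.049
female,adipose,18.0,0.31666666666666665,0.05
female,bone,0.0,0.08,0.03
female,bone,0.5,0.085,0.033
female,bone,1.0,0.09,0.035
female,bone,2.0,0.1,0.038
female,bone,5.0,0.11,0.042
female,bone,10.0,0.12,0.046
female,bone,15.0,0.135,0.049
female,bone,18.0,0.12666666666666665,0.05
female,brain,0.0,0.109,0.15
female,brain,0.5,0.088,0.25
female,brain,1.0,0.095,0.27
female,brain,2.0,0.081,0.26
female,brain,5.0,0.066,0.23
female,brain,10.0,0.042,0.18
female,brain,15.0,0.025,0.13
female,brain,18.0,0.021666666666666667,0.12
female,gut,0.0,0.012,0.14
female,gut,0.5,0.013,0.142
female,gut,1.0,0.0135,0.144
female,gut,2.0,0.014,0.146
female,gut,5.0,0.0145,0.148
female,gut,10.0,0.015,0.149
female,gut,15.0,0.0158,0.15
female,gut,18.0,0.016666666666666666,0.15
female,heart,0.0,0.0057,0.03
female,heart,0.5,0.0055,0.032
female,heart,1.0,0.005,0.033
female,heart,2.0,0.0048,0.035
female,heart,5.0,0.0045,0.037
female,heart,10.0,0.0044,0.039
female,heart,15.0,0.0044,0.04
female,heart,18.0,0.004166666666666667,0.04
female,liver,0.0,0.0371,0.06
female,liver,0.5,0.04,0.061
female,liver,1.0,0.033,0.062
female,liver,2.0,0.03,0.062
female,liver,5.0,0.029,0.063
female,liver,10.0,0.027,0.064
female,liver,15.0,0.0245,0.065
female,liver,18.0,0.02333333333333333,0.065
female,lung,0.0,0.0171,1.0
female,lung,0.5,0.0145,1.0
female,lung,1.0,0.013,1.0
female,lung,2.0,0.011,1.0
female,lung,5.0,0.0095,1.0
female,lung,10.0,0.0085,1.0
female,lung,15.0,0.0078,1.0
female,lung,18.0,0.007,1.0
female,muscle,0.0,0.22,0.08
female,muscle,0.5,0.22,0.085
female,muscle,1.0,0.23,0.09
female,muscle,2.0,0.26,0.1
female,muscle,5.0,0.31,0.12
female,muscle,10.0,0.35,0.145
female,muscle,15.0,0.4,0.165
female,muscle,18.0,0.2916666666666667,0.17
female,skin,0.0,0.05,0.06
female,skin,0.5,0.048,0.058
female,skin,1.0,0.045,0.056
female,skin,2.0,0.043,0.054
female,skin,5.0,0.042,0.052
female,skin,10.0,0.044,0.051
female,skin,15.0,0.046,0.05
female,skin,18.0,0.03833333333333333,0.05
female,spleen,0.0,0.00286,0.03
female,spleen,0.5,0.0027,0.03
female,spleen,1.0,0.0026,0.03
female,spleen,2.0,0.0025,0.03
female,spleen,5.0,0.0024,0.03
female,spleen,10.0,0.0023,0.03
female,spleen,15.0,0.0022,0.03
female,spleen,18.0,0.0021666666666666666,0.03
female,pancreas,0.0,0.00171,0.01
female,pancreas,0.5,0.0018,0.01
female,pancreas,1.0,0.00185,0.01
female,pancreas,2.0,0.0019,0.01
female,pancreas,5.0,0.00195,0.01
female,pancreas,10.0,0.00198,0.01
female,pancreas,15.0,0.002,0.01
female,pancreas,18.0,0.002,0.01
female,kidney,0.0,0.0071,
female,kidney,0.5,0.0068,
female,kidney,1.0,0.0065,
female,kidney,2.0,0.006,
female,kidney,5.0,0.0055,
female,kidney,10.0,0.005,
female,kidney,15.0,0.0046,
female,kidney,18.0,0.004666666666666667,
female,kidney,0.0,,0.06511627906976744
female,kidney,0.25,,0.07758620689655173
female,kidney,0.5,,0.08703703703703702
female,kidney,1.0,,0.099
female,kidney,1.5,,0.10967741935483871
female,kidney,2.0,,0.12093023255813953
female,kidney,3.0,,0.12853835978835979
female,kidney,4.0,,0.13536641929499074
female,kidney,5.0,,0.14101110038610037
female,kidney,6.0,,0.14610389610389612
female,kidney,7.0,,0.15047533401849947
female,kidney,8.0,,0.1539653361344538
female,kidney,9.0,,0.1576127819548872
female,kidney,10.0,,0.16142857142857145
female,kidney,11.0,,0.1646467756381549
female,kidney,12.0,,0.1679883614787768
female,kidney,13.0,,0.17146056305258262
female,kidney,14.0,,0.17507119126720458
female,kidney,15.0,,0.1788286924939467
female,kidney,16.0,,0.18242659758203797
female,kidney,17.0,,0.18616385814889336
female,kidney,18.0,,0.18999999999999997
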