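sex,body_weight_kg,blood_l,cardiac_output_l_h,hematocrit
male,70.0,5.3,390.0,0.45
female,60.0,4.1,354.0,0.4
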