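organ,f_water_extracellular,f_water_intracellular,f_neutral_lipid,f_neutral_phospholipid,conc_acidic_phospholipid_mg_g,intracellular_ph
adipose,0.135,0.017,0.845,0.0016,0.4,7.0
bone,0.1,0.346,0.017,0.0017,0.67,7.0
brain,0.162,0.62,0.0391,0.0015,0.4,7.0
gut,0.282,0.475,0.0487,0.0163,2.41,7.0
heart,0.32,0.456,0.0115,0.0166,2.25,7.0
kidney,0.273,0.483,0.0207,0.0162,5.03,7.0
liver,0.161,0.573,0.0348,0.0252,4.56,7.0
lung,0.336,0.446,0.0219,0.0148,3.91,7.0
muscle,0.118,0.63,0.0238,0.0072,1.53,7.0
skin,0.382,0.291,0.0284,0.0111,1.32,7.0
spleen,0.207,0.579,0.0201,0.0198,3.18,7.0
pancreas,0.12,0.664,0.0403,0.009,1.67,7.0
rest,0.15,0.55,0.04,0.008,1.5,7.0
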