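sex,age_y,weight_median_kg,weight_gsd,height_median_cm,height_gsd
male,0.0,3.3,1.135,49.9,1.042
male,0.02,3.6,1.135,51.1,1.042
male,0.083,4.5,1.135,54.7,1.042
male,0.25,6.4,1.135,61.4,1.042
male,0.5,7.9,1.135,67.6,1.042
male,1.0,9.6,1.135,75.7,1.042
male,2.0,12.2,1.135,87.1,1.042
male,3.0,14.3,1.135,96.1,1.042
male,5.0,18.3,1.135,109.2,1.042
male,7.0,22.9,1.135,121.7,1.042
male,10.0,31.2,1.135,138.6,1.042
male,12.0,39.8,1.135,149.1,1.042
male,14.0,50.8,1.135,163.2,1.042
male,16.0,60.8,1.135,173.4,1.042
male,18.0,68.0,1.135,176.1,1.042
female,0.0,3.2,1.135,49.1,1.042
female,0.02,3.4,1.135,50.3,1.042
female,0.083,4.2,1.135,53.7,1.042
female,0.25,5.8,1.135,59.8,1.042
female,0.5,7.3,1.135,65.7,1.042
female,1.0,8.9,1.135,74.0,1.042
female,2.0,11.5,1.135,85.7,1.042
female,3.0,13.9,1.135,95.1,1.042
female,5.0,18.0,1.135,108.4,1.042
female,7.0,22.4,1.135,121.1,1.042
female,10.0,31.9,1.135,138.4,1.042
female,12.0,41.5,1.135,151.2,1.042
female,14.0,49.4,1.135,160.4,1.042
female,16.0,53.5,1.135,162.5,1.042
female,18.0,57.0,1.135,163.0,1.042
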