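patient_id,age,sex,Ki_s,r2_Ki_s,SUV
1,64,M,0.0646,0.9985,11.56
2,80,M,0.1018,0.9915,19.64
3,76,M,0.0374,0.9920,9.26
4,73,M,0.1188,0.9954,19.89
5,84,M,0.0614,0.9939,12.61
6,71,F,0.0697,0.9902,15.35
7,72,M,0.0485,0.9446,7.15
8,47,M,0.0971,0.9183,14.96
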