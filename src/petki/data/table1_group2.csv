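patient_id,age,sex,Ki,r2_Ki,Ki_s,r2_Ki_s,SUV
2,75,M,0.0314,0.9838,0.0291,0.9748,7.69
4,74,M,0.0381,0.9900,0.0377,0.9873,11.28
6,73,M,0.0385,0.9475,0.0361,0.9808,7.86
9,77,M,0.0468,0.9820,0.0485,0.9833,14.32
11,73,F,0.0403,0.9983,0.0418,0.9965,10.29
13,70,M,0.0383,0.9572,0.0349,0.9545,8.75
15,74,F,0.0222,0.9342,0.0222,0.9364,9.10
18,72,F,0.0165,0.9812,0.0166,0.9839,5.88
21,81,M,0.0310,0.9640,0.0290,0.9593,5.97
24,40,F,0.0303,0.9952,0.0313,0.9953,5.83
25,74,M,0.0764,0.9813,0.0733,0.9859,15.20
26,61,M,0.0656,0.9906,0.0654,0.9951,11.60
27,64,M,0.1306,0.9941,0.1287,0.9936,25.92
31,58,F,0.0123,0.9782,0.0117,0.9877,4.46
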