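patient_id,outcome,d_score,delta
P1,good,9.746,38.38
P2,poor,-2.504,-33.93
P3,good,1.729,38.42
P4,good,0.811,15.82
P5,good,-0.894,-7.03
P6,good,5.1529,106.66
P7,good,-1.911,-23.81
P8,good,-0.174,-2.751
P9,good,0.5147,4.42
P10,poor,0.299,4.61
P11,poor,-0.322,-13.29
P12,poor,-0.576,-11.75
P13,poor,0.038,2.664
P14,poor,-6.005,-185.37
P15,poor,-4.934,-118.84
P16,poor,-2.062,-8.921
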