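label,half_life_min,dataset1,dataset2
WT,6.9,1,1
I77L,20.1,1,1
Q97E,16.5,1,1
F115L,17.2,0,1
L118T,26.1,0,1
E133A,9.8,0,1
H210N,23.1,1,1
N245D,14.8,1,1
E253A,11.8,0,1
G292D,14.8,1,1
I295V,9.3,1,1
F115L_L118T,65.9,0,1
I77L_H210N,42.2,1,1
Q97E_H210N,30.6,1,1
H210N_N245D,18.4,1,1
H210N_G292D,33.6,1,1
I77L_Q97E_H210N,31,1,1
I77L_H210N_G292D,16.7,1,1
I77L_Q97E_H210N_N245D,14.4,0,1
I77L_H210N_N245D_G292D,16.3,0,1
I77L_Q97E_H210N_N245D_G292D,8.7,0,1
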