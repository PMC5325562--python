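question,neg_1,neg_2,neg_3,neg_4,pos_1,pos_2,pos_3,pos_4,p_value
Q1,9,8,4,10,16,14,14,15,0.66
Q2a,0,0,0,1,16,14,14,14,0.73
Q2b,0,0,0,1,0,0,0,0,
Q3a,2,3,1,2,14,11,13,11,0.79
Q3b,1,0,0,1,1,3,1,1,0.57
Q4a,6,8,13,4,9,6,1,8,0.008
Q4b,6,1,11,4,0,7,2,0,<0.001
Q5a,9,6,1,7,0,0,0,1,0.63
Q5b,8,13,2,7,1,0,1,0,0.15
Q6,0,1,0,0,8,12,2,7,1.00
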