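method,rater_a,rater_b,n,exact_agreement,extreme_disagreement,kappa,kappa_linear
WHO-UMC,1,2,7,1.0,0,1.0,1.0
WHO-UMC,1,3,8,0.50,0,0.35,0.53
WHO-UMC,1,4,6,1.0,0,1.0,1.0
WHO-UMC,2,3,10,0.60,0.10,0.49,0.67
WHO-UMC,2,4,9,0.56,0.11,0.33,0.52
WHO-UMC,3,4,8,0.75,0.13,0.60,0.77
LCAT,1,2,8,0.25,0.13,0.094,0.22
LCAT,1,3,9,0.33,0,0.13,0.077
LCAT,1,4,10,0.80,0.10,0.71,0.88
LCAT,2,3,6,0.33,0.17,0.14,0.35
LCAT,2,4,8,0.50,0.13,0.27,0.55
LCAT,3,4,7,0.43,0.43,0.32,0.55
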