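category,definite,probable,possible,unlikely,unassessable
definite,1,1,0,0,0
probable,0,8,9,2,1
possible,0,0,3,9,1
unlikely,0,0,0,9,3
unassessable,0,0,0,0,1
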