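category,definite,probable,possible,unlikely,unassessable
definite,4,0,0,0,0
probable,0,3,4,0,1
possible,0,0,9,7,1
unlikely,0,0,0,13,1
unassessable,0,0,0,0,5
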