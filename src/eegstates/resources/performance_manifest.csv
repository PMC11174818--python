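subject_id,score,group,excluded
S27,34.59,G,False
S13,34,G,False
S3,31,G,False
S34,31,G,False
S25,30.53,G,False
S1,29.35,G,False
S17,28.7,G,False
S23,27.47,G,False
S28,27,G,False
S12,26.36,G,False
S11,26,G,False
S15,22.18,G,False
S33,21.47,G,False
S5,20.71,G,False
S18,20,G,False
S31,19.88,G,True
S8,18.24,G,False
S29,16.59,G,False
S20,15.41,G,False
S24,14.76,G,False
S26,13.59,G,False
S7,13.38,G,False
S32,13,G,False
S2,12.88,G,False
S35,12.18,G,False
S16,11.59,G,False
S30,10,B,False
S0,9.7,B,False
S14,9,B,False
S4,8.6,B,True
S19,7.06,B,False
S9,7,B,False
S22,4.47,B,False
S6,4.35,B,False
S10,1,B,False
S21,1,B,False
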