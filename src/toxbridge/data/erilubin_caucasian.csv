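# drug: Erilubin
# population: Caucasian
dose,n_dlt,n_patients
0.25,0,1
0.5,0,4
1.0,0,3
2,1,7
2.8,2,3
4,3,3
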