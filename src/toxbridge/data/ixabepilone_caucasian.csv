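# drug: Ixabepilone
# population: Caucasian
dose,n_dlt,n_patients
7.4,0,3
15,0,3
30,0,3
50,3,22
57,3,3
65,2,3
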