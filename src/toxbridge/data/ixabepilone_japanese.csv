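# drug: Ixabepilone
# population: Japanese
dose,n_dlt,n_patients
15,0,3
30,0,3
40,1,6
50,2,2
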