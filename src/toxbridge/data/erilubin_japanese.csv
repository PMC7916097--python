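# drug: Erilubin
# population: Japanese
dose,n_dlt,n_patients
0.7,0,3
1.0,0,3
1.4,2,6
2,3,3
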