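# drug: Synthetic
# population: Caucasian
# declared_mtd: 600
dose,n_dlt,n_patients
100,0,3
200,0,3
400,0,6
600,3,9
800,2,3
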