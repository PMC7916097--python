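# drug: Synthetic-3
# population: Japanese
# declared_mtd: 200
dose,n_dlt,n_patients
100,0,3
200,1,6
400,3,3
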