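# drug: Synthetic-2
# population: Japanese
# declared_mtd: 600
dose,n_dlt,n_patients
400,0,3
500,0,9
600,4,12
800,3,3
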