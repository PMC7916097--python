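# drug: Synthetic-1
# population: Japanese
# declared_mtd: 600
dose,n_dlt,n_patients
500,1,10
600,2,8
800,2,2
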