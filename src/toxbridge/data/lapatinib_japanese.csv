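# drug: Lapatinib
# population: Japanese
dose,n_dlt,n_patients
900,0,6
1200,0,6
1600,1,6
1800,1,6
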