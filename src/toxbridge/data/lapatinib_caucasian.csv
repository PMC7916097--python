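# drug: Lapatinib
# population: Caucasian
dose,n_dlt,n_patients
500,0,13
650,1,15
900,0,11
1000,1,3
1200,1,12
1600,1,13
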