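# drug: Edotecarin
# population: Caucasian
dose,n_dlt,n_patients
6,0,3
8,0,3
11,0,6
13,1,9
15,4,9
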