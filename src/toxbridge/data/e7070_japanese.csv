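# drug: E7070
# population: Japanese
dose,n_dlt,n_patients
400,0,3
600,0,3
700,0,6
800,1,6
900,2,3
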