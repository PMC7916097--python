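# drug: E7070
# population: Caucasian
dose,n_dlt,n_patients
50,0,4
100,0,3
200,0,3
400,0,3
600,0,4
700,2,7
800,2,4
1000,3,3
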