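# drug: Sorafenib
# population: Caucasian
# note: doses in mg bid; numeric values stored as printed, units opaque to the method
dose,n_dlt,n_patients
100,0,3
200,1,6
400,0,8
600,3,7
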