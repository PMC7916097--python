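# drug: Sorafenib
# population: Japanese
# declared_mtd: 400
# note: doses in mg bid; numeric values stored as printed, units opaque to the method
dose,n_dlt,n_patients
100,0,3
200,1,12
400,0,6
600,1,6
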