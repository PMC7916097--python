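# drug: Edotecarin
# population: Japanese
# note: the published 15 mg/m2 cell is garbled '2/62/6'; read as 2 DLTs / 6 patients (see *_alt fixture)
dose,n_dlt,n_patients
8,0,3
11,1,6
13,1,9
15,2,6
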