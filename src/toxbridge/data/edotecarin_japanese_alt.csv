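# drug: Edotecarin
# population: Japanese
# note: alternate reading of the garbled 15 mg/m2 cell as two cohorts 2/6 + 2/6 = 4/12
dose,n_dlt,n_patients
8,0,3
11,1,6
13,1,9
15,4,12
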