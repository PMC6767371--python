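study_id,mean0,sd0,n0,mean1,sd1,n1
Basun 1991,114,25,26,100,39,20
Kristensen 1993,89,32,20,90,33,26
Modashi 1996,63,30,421,56,22,31
Molina 1998,101,31,28,114,35,26
Vural 2010,81,31,50,67,23,50
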