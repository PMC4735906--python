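enzyme	Vc	Kc	Ko	tau
ancestral_form_1A	4.77	113	2010	54.7
ancestral_form_1B	4.72	120	641	49.6
prochlorococcus_form_1A	6.58	309	1400	59.9
synechococcus_form_1B	9.78	152	1231	50.3
wheat	2.92	10.9	341	100.0
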