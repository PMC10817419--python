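predicted\gold	no_otitis	otitis_not_media	om_not_acute	aom	aom_perforation	aom_recurrent
no_otitis	155	0	2	0	0	0
otitis_not_media	7	168	7	0	0	0
om_not_acute	1	0	101	1	1	0
aom	2	1	1	389	6	0
aom_perforation	0	0	0	1	28	0
aom_recurrent	0	0	0	0	0	9
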