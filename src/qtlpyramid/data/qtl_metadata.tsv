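name	donor_species	chromosome_tag	linked_group
qSER1a-gla	glaberrima	1
qSER1b-gla	glaberrima	1
qSER1b-glu	glumaepatula	1
qSER2a-sat	sativa	2	A35-segment
qSER2b-sat	sativa	2	A35-segment
qSER3a-sat	sativa	3	A88-segment
qSER3b-sat	sativa	3	A88-segment
qSER3b-glu	glumaepatula	3
qSER5-glu	glumaepatula	5
qSER8b-gla	glaberrima	8
qSER12-gla	glaberrima	12
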