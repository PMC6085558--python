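subject	group	time	event
s1	A	1	1
s2	B	2	1
s3	A	3	1
s4	B	4	0
s5	A	5	0
s6	B	6	1
s7	A	7	1
s8	B	8	1
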