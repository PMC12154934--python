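protein_id	chain_id	length
2CCI	F	30
1SGH	B	39
1MZW	B	31
6F4U	D	40
1OQE	K	31
2L9U	A	40
5KQ1	C	31
5OM2	B	40
5JPO	E	32
2XZE	R	40
2L34	A	33
4LZX	B	40
6B7G	B	33
5TUV	C	41
3MJH	B	34
2XA6	A	41
4NAW	D	34
2MOF	A	42
3DXC	B	35
2K9J	B	43
2XJY	B	35
2F9D	P	43
2BE6	D	37
4GDO	A	43
1IK9	C	37
6GNY	B	43
5XJL	M	37
6AU8	C	43
5FV8	E	38
2KS1	A	44
4UED	B	38
3HRO	A	44
5FV8	A	38
2L2T	A	44
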