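letter	hydrophobicity	molecular_mass	vdw_volume	dipole_moment	aromatic	acid_base
A	1.8	71	67	5.937	false	neither
C	2.5	103	86	10.74	false	neither
D	-3.5	115	91	29.49	false	acidic
E	-3.5	129	109	42.52	false	acidic
F	2.8	147	135	5.98	true	neither
G	-0.4	57	48	0.0	false	neither
H	-3.2	137	118	20.44	false	basic
I	4.5	113	124	3.371	false	neither
K	-3.9	128	135	50.02	false	basic
L	3.8	113	124	3.782	false	neither
M	1.9	131	124	8.589	false	neither
N	-3.5	114	96	18.89	false	neither
P	-1.6	97	90	7.916	false	neither
Q	-3.5	128	114	39.89	false	neither
R	-4.5	156	148	37.5	false	basic
S	-0.8	87	73	9.836	false	neither
T	-0.7	101	93	9.304	false	neither
V	4.2	99	105	2.692	false	neither
W	-0.9	186	163	10.73	true	neither
Y	-1.3	163	141	10.41	true	neither
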