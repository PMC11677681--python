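# Seven per-residue physicochemical descriptors (standard literature scales):
# sheet_prob / helix_prob: Chou-Fasman-style conformational propensities;
# pI: isoelectric point; hydrophobicity: octanol scale; vdw_volume:
# normalized van der Waals volume; polarizability; graph_shape: steric
# parameter (graph shape index).  X carries the column means of the 20
# standard residues.
aa	sheet_prob	helix_prob	pI	hydrophobicity	vdw_volume	polarizability	graph_shape
A	0.23	0.42	6.11	0.31	1.00	0.05	1.28
C	0.41	0.17	6.35	1.54	2.43	0.13	1.77
D	0.20	0.25	2.95	-0.77	2.78	0.11	1.60
E	0.21	0.42	3.09	-0.64	3.78	0.15	1.56
F	0.38	0.30	5.67	1.79	5.89	0.29	2.94
G	0.15	0.13	6.07	0.00	0.00	0.00	0.00
H	0.30	0.27	7.69	0.13	4.66	0.23	2.99
I	0.45	0.30	6.04	1.80	4.00	0.19	4.19
K	0.27	0.32	9.99	-0.99	4.77	0.22	1.89
L	0.31	0.39	6.04	1.70	4.00	0.19	2.59
M	0.32	0.38	5.71	1.23	4.43	0.22	2.35
N	0.22	0.21	6.52	-0.60	2.95	0.13	1.60
P	0.34	0.13	6.80	0.72	2.72	0.00	2.67
Q	0.25	0.36	5.65	-0.22	3.95	0.18	1.56
R	0.25	0.36	10.74	-1.01	6.13	0.29	2.34
S	0.28	0.20	5.70	-0.04	1.60	0.06	1.31
T	0.36	0.21	5.60	0.26	2.60	0.11	3.03
V	0.49	0.27	6.02	1.22	3.00	0.14	3.67
W	0.42	0.32	5.94	2.25	8.08	0.41	3.21
Y	0.41	0.25	5.66	0.96	6.47	0.30	2.94
X	0.3025	0.2780	6.2170	0.4820	3.7620	0.1745	2.2745
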