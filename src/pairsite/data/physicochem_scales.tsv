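# Per-amino-acid physicochemical scale table, version 1.
# Columns 2-13 are the 12 sequence-level descriptor scales; the last two
# columns are the residue-volume scale and the reference maximum ASA used
# to normalize relative SASA. Sources (pinned, see docs/methods.md):
# hydrophilicity Hopp-Woods 1981; flexibility Vihinen 1994; accessibility
# Janin 1979; turns Chou-Fasman 1978; exposed_surface Emini 1985;
# antigenicity Welling 1985; net_charge_index NCISC; polarizability
# Charton-Charton 1982; hydrophobicity Fauchere-Pliska 1983 + Kyte-
# Doolittle 1982; polarity Grantham 1974 + Zimmerman 1968; side-chain
# volume Zamyatnin 1972; max_asa Tien 2013 (theoretical).
aa	hydrophilicity	flexibility	accessibility	turns	exposed_surface	antigenicity	net_charge_index	polarizability	hydrophobicity_h1	hydrophobicity_h2	polarity_p1	polarity_p2	side_chain_volume	max_asa
A	-0.5	0.984	0.28	0.66	0.815	1.15	0.007187	0.046	0.31	1.8	8.1	0	88.6	129
R	3	1.008	-1.14	0.95	1.475	0.58	0.043587	0.291	-1.01	-4.5	10.5	52	173.4	274
N	0.2	1.048	-0.55	1.56	1.296	-0.77	0.005392	0.134	-0.6	-3.5	11.6	3.38	114.1	195
D	3	1.068	-0.52	1.46	1.283	0.65	-0.02382	0.105	-0.77	-3.5	13	49.7	111.1	193
C	-1	0.906	0.97	1.19	0.394	-1.2	-0.03661	0.128	1.54	2.5	5.5	1.48	108.5	167
Q	0.2	1.037	-0.69	0.98	1.348	-0.11	0.049211	0.18	-0.22	-3.5	10.5	3.53	143.8	225
E	3	1.094	-1.01	0.74	1.445	-0.71	0.006802	0.151	-0.64	-3.5	12.3	49.9	138.4	223
G	0	1.031	0.43	1.56	0.714	-1.84	0.179052	0	0	-0.4	9	0	60.1	104
H	-0.5	0.95	-0.31	0.95	1.18	3.12	-0.01069	0.23	0.13	-3.2	10.4	51.6	153.2	224
I	-1.8	0.927	0.6	0.47	0.603	-2.92	0.021631	0.186	1.8	4.5	5.2	0.13	166.7	197
L	-1.8	0.935	0.6	0.59	0.603	0.75	0.051672	0.186	1.7	3.8	4.9	0.13	166.7	201
K	3	1.102	-1.62	1.01	1.545	2.06	0.017708	0.219	-0.99	-3.9	11.3	49.5	168.6	236
M	-1.3	0.952	0.43	0.6	0.714	-3.85	0.002683	0.221	1.23	1.9	5.7	1.43	162.9	224
F	-2.5	0.915	0.46	0.6	0.695	-1.41	0.037552	0.29	1.79	2.8	5.2	0.35	189.9	240
P	0	1.049	-0.42	1.52	1.236	-0.53	0.239531	0.131	0.72	-1.6	8	1.58	112.7	159
S	0.3	1.046	-0.19	1.43	1.115	-0.26	0.004627	0.062	-0.04	-0.8	9.2	1.67	89	155
T	-0.4	0.997	-0.32	0.96	1.184	-0.45	0.003352	0.108	0.26	-0.7	8.6	1.66	116.1	172
W	-3.4	0.904	0.29	0.96	0.808	-1.14	0.037977	0.409	2.25	-0.9	5.4	2.1	227.8	285
Y	-2.3	0.929	-0.15	1.14	1.089	0.13	0.023599	0.298	0.96	-1.3	6.2	1.61	193.6	263
V	-1.5	0.931	0.6	0.5	0.606	-0.13	0.057004	0.14	1.22	4.2	5.9	0.13	140	174
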