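property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydropathy_kyte_doolittle	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
polarity_grantham	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
volume_grantham	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
composition_grantham	0	2.75	1.38	0.92	0	0.74	0.58	0	0.33	0	0	1.33	0.39	0.89	0.65	1.42	0.71	0	0.13	0.2
residue_molecular_weight	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.1	97.12	128.13	156.19	87.08	101.1	99.13	186.21	163.18
isoelectric_point	6.0	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.6	5.96	5.89	5.66
hydrophilicity_hopp_woods	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
bulkiness_zimmerman	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
helix_propensity_chou_fasman	1.42	0.7	1.01	1.51	1.13	0.57	1.0	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
sheet_propensity_chou_fasman	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
turn_propensity_chou_fasman	0.66	1.19	1.46	0.74	0.6	1.56	0.95	0.47	1.01	0.59	0.6	1.56	1.52	0.98	0.95	1.43	0.96	0.5	0.96	1.14
refractivity_jones	4.34	35.77	12.0	17.26	29.4	0.0	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
polar_requirement_woese	7.0	4.8	13.0	12.5	5.0	7.9	8.4	4.9	10.1	4.9	5.3	10.0	6.6	8.6	9.1	7.5	6.6	5.6	5.2	5.4
vdw_volume_fauchere	1.0	2.43	2.78	3.78	5.89	0.0	4.66	4.0	4.77	4.0	4.43	2.95	2.72	3.95	6.13	1.6	2.6	3.0	8.08	6.47
hydrophobicity_fauchere_pliska	0.31	1.54	-0.77	-0.64	1.79	0.0	0.13	1.8	-0.99	1.7	1.23	-0.6	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
net_charge_ph7	0	0	-1	-1	0	0	0.1	0	1	0	0	0	0	0	1	0	0	0	0	0
pk_alpha_carboxyl	2.34	1.96	1.88	2.19	1.83	2.34	1.82	2.36	2.18	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.09	2.32	2.83	2.2
pk_alpha_amino	9.69	10.28	9.6	9.67	9.13	9.6	9.17	9.6	8.95	9.6	9.21	8.8	10.6	9.13	9.04	9.15	9.1	9.62	9.39	9.11
buried_fraction_chothia	0.38	0.45	0.15	0.18	0.5	0.36	0.17	0.6	0.03	0.45	0.4	0.12	0.18	0.07	0.01	0.22	0.23	0.54	0.27	0.15
accessible_surface_area	113	140	151	183	218	85	194	182	211	180	204	158	143	189	241	122	146	160	259	229
flexibility_bhaskaran	0.36	0.35	0.51	0.5	0.31	0.54	0.32	0.46	0.47	0.37	0.3	0.46	0.51	0.49	0.53	0.51	0.44	0.39	0.31	0.42
aromaticity	0	0	0	0	1	0	0.5	0	0	0	0	0	0	0	0	0	0	0	1	1
aliphaticity	1	0	0	0	0	0	0	1	0	1	0.5	0	0	0	0	0	0	1	0	0
sidechain_hbond_donors	0	1	1	1	0	0	2	0	3	0	0	2	0	2	4	1	1	0	1	1
sidechain_hbond_acceptors	0	1	4	4	0	0	2	0	0	0	1	2	0	2	0	2	2	0	1	2
polarity_zimmerman	0.0	1.48	49.7	49.9	0.35	0.0	51.6	0.13	49.5	0.13	1.43	3.38	1.58	3.53	52.0	1.67	1.66	0.13	2.1	1.61
hydration_potential_wolfenden	1.94	-1.24	-10.95	-10.2	-0.76	2.39	-10.27	2.15	-9.52	2.28	-1.48	-9.68	0.0	-9.38	-19.92	-5.06	-4.88	1.99	-5.88	-6.11
transfer_energy_janin	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
helix_penalty_pace	0.0	0.68	0.69	0.4	0.54	1.0	0.61	0.41	0.26	0.21	0.24	0.65	3.16	0.39	0.21	0.5	0.66	0.61	0.49	0.53
beta_branching	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	1	1	0	0
sulfur_content	0	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
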