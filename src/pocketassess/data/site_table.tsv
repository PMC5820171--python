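site_id	target_id	n_centers	category	subtype	ligand	rmsd_min	rmsd_max	n_servers	classification
T0861	T0861	28	holo	ligand	LLP	0.945	26.170	42	TBM
T0863	T0863	8	holo	ligand	CLR	4.686	284.38	90	FM
T0873	T0873	24	holo	ligand	FMN	2.656	109.89	41	TBM
T0879	T0879	7	holo	ligand	ZN	4.213	40.255	39	TBM
T0889	T0889	21	holo	ligand	SOR	2.591	44.685	38	TBM
T0891	T0891	11	holo	ligand	HEM	2.314	29.119	40	TBM
T0893	T0893	22	holo	ligand	ADP	9.251	51.388	43	TBM
T0910	T0910	27	holo	ligand	ANP	2.540	45.013	40	TBM
T0911	T0911	10	holo	ligand	GCO	4.377	193.48	105	TBM
T0880-0	T0880	14	apo	apo		8.492	59.427	108	FM
T0880-1	T0880	13	apo	apo		8.492	59.427	108	FM
T0894	T0894	19	apo	apo		5.064	68.908	98	TBM
T0895	T0895	21	apo	apo		4.353	24.348	110	TBM
T0896	T0896	23	apo	apo		5.030	150.96	98	TBM
T0913	T0913	13	apo	apo		3.955	42.81	108	TBM
T0917	T0917	73	apo	apo		2.564	44.06	43	TBM
T0942	T0942	10	apo	apo		2.992	72.043	92	TBM
T0947	T0947	25	apo	apo		5.292	33.782	97	TBM
T0860	T0860	17	patch	motif		2.654	54.506	42	TBM
T0864	T0864	11	patch	key_residues		10.34	139.28	101	FM
T0882	T0882	11	patch	key_residues		2.306	25.381	116	TBM
T0914	T0914	26	patch	key_residues		13.53	127.45	97	FM
T0915	T0915	14	patch	key_residues		5.42	40.854	108	FM
T0920-0	T0920	31	patch	key_residues		3.213	180.13	39	TBM
T0920-1	T0920	14	patch	key_residues		3.213	180.13	39	TBM
T0943-1	T0943	9	patch	motif		6.497	77.188	40	TBM
T0943-2	T0943	10	patch	motif		6.497	77.188	40	TBM
T0948	T0948	15-19	patch	mutation		3.092	36.111	95	TBM
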