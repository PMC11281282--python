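description	symbol	gene_id	log2fc	pvalue	padj	panel
Collagen type I alpha 1 chain	COL1A1	1277	2.63	5.27e-19	0.0000	ECM
Fibronectin type III domain containing 1	FNDC1	84624	1.97	2.44e-11	0.0000	ECM
Collagen type I alpha 2 chain	COL1A2	1278	1.93	3.44e-14	0.0000	ECM
Laminin subunit beta 3	LAMB3	3914	1.64	4.20e-10	0.0000	ECM
Laminin subunit gamma 2	LAMC2	3918	1.62	5.88e-07	0.0000	ECM
Nidogen 2	NID2	22795	1.51	2.04e-13	0.0000	ECM
Aggrecan	ACAN	176	1.50	3.76e-05	0.0003	ECM
EGF-like, fibronectin type III and Laminin G domains	EGFLAM	133584	1.39	3.38e-12	0.0000	ECM
Laminin subunit beta 4	LAMB4	22798	1.36	6.52e-06	0.0001	ECM
Laminin subunit alpha 1	LAMA1	284217	0.75	7.09e-03	0.0228	ECM
Laminin subunit beta 1	LAMB1	3912	0.73	4.16e-05	0.0003	ECM
Laminin subunit alpha 4	LAMA4	3910	0.52	2.84e-03	0.0108	ECM
Hyaluronan binding protein 2	HABP2	3026	-2.37	8.10e-07	0.0000	ECM
HHIP like 2 (myCAF)	HHIPL2	79802	3.27	1.44e-14	0.0000	CAF
Leucine-rich repeat containing 15 (myCAF)	LRRC15	131578	2.37	6.07e-10	0.0000	CAF
Thy-1 cell surface antigen (myCAF)	THY1	7070	1.44	1.02e-13	0.0000	CAF
Fibroblast activation protein alpha	FAP	2191	1.40	5.33e-09	0.0000	CAF
HHIP like 1 (myCAF)	HHIPL1	84439	0.85	2.06e-05	0.0002	CAF
Platelet derived growth factor receptor beta (iCAF)	PDGFRB	5159	0.55	9.45e-04	0.0044	CAF
Integrin subunit alpha 8 (apCAF)	ITGA8	8516	-0.82	3.29e-05	0.0003	CAF
Lymphocyte activating 3	LAG3	3902	1.62	2.81e-10	0.0000	immune_checkpoint
Indoleamine 2,3-dioxygenase 1	IDO1	3620	1.60	2.73e-06	0.0000	immune_checkpoint
Sialic acid binding Ig like lectin 10	SIGLEC10	89790	1.35	4.07e-07	0.0000	immune_checkpoint
V-set domain containing T cell activation inhibitor 1	VTCN1	79679	1.33	1.30e-02	0.0373	immune_checkpoint
Programmed cell death 1	PDCD1	5133	1.09	2.36e-05	0.0002	immune_checkpoint
CD274 molecule	CD274	29126	0.68	1.55e-02	0.0430	immune_checkpoint
Interferon gamma (Th1, Tc1)	IFNG	3458	1.80	1.32e-05	0.0001	T_cell
Transforming growth factor beta induced (Tregs)	TGFBI	7045	1.11	1.06e-08	0.0000	T_cell
CD8b molecule (Tc)	CD8B	926	0.85	1.69e-03	0.0070	T_cell
Interleukin 2 receptor subunit alpha (Tregs, Tcm)	IL2RA	3559	0.84	3.54e-03	0.0129	T_cell
Integrin subunit alpha E (Trm, RTE)	ITGAE	3682	0.82	4.69e-07	0.0000	T_cell
CD38 molecule (activated T cells)	CD38	952	0.71	2.01e-02	0.0531	T_cell
CD8a molecule (Tc)	CD8A	925	0.69	7.49e-03	0.0238	T_cell
Interleukin 10 (Tregs, Trm, Th2, Tc9)	IL10	3586	0.68	6.95e-03	0.0224	T_cell
CD3 delta subunit of T-cell receptor complex (Pan T cells)	CD3D	915	0.60	6.17e-03	0.0204	T_cell
Interleukin 2 receptor subunit beta (Tscm, Tcm, Tem, Teff)	IL2RB	3560	0.59	1.21e-02	0.0351	T_cell
C-C motif chemokine receptor 6 (Th17, Tc17)	CCR6	1235	-0.59	3.2e-03	0.0119	T_cell
prostaglandin D2 receptor 2 (Th2, Tc2)	PTGDR2	11251	-0.72	1.20e-02	0.0348	T_cell
CD69 molecule (Trm, Tcm, Tem, Teff)	CD69	969	-0.72	2.08e-03	0.0083	T_cell
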