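SNP	CHR	BP	GENE	EA	EAF_EUR	BETA_EUR	EAF_CHINESE	BETA_CHINESE	P_CHINESE	EAF_MALAY	BETA_MALAY	P_MALAY	EAF_INDIAN	BETA_INDIAN	P_INDIAN	EAF_META	BETA_META	P_META	SOURCE
rs2779116	1	156852039	SPTA1	T	0.27	0.024	0.43	0.016	3.72E-02	0.46	0.012	3.40E-01	0.16	-0.015	3.72E-01	0.40	0.011	6.99E-02	literature
rs1402837	2	169465600	G6PC2	T	0.23	0.023	0.41	0.008	3.11E-01	0.38	0.034	8.05E-03	0.22	0.018	2.28E-01	0.37	0.016	1.10E-02	literature
rs552976	2	169499684	G6PC2,ABCB11	G	0.64	0.047	0.99	-0.036	3.24E-01	0.97	0.046	2.00E-01	0.83	0.014	3.88E-01	0.87	0.012	3.96E-01	literature
rs730497	7	44190246	GCK	G	0.83	-0.030	0.80	-0.039	8.57E-05	0.88	-0.059	2.97E-03	0.88	-0.045	2.05E-02	0.83	-0.043	8.14E-08	literature
rs1799884	7	44195593	GCK	T	0.18	0.038	0.20	0.039	7.49E-05	0.11	0.061	2.16E-03	0.12	0.045	2.09E-02	0.17	0.044	5.62E-08	literature
rs6474359	8	41668351	ANK1	T	0.97	0.058	0.97	0.003	8.80E-01	0.98	-0.003	9.53E-01	0.97	0.025	5.59E-01	0.97	0.007	7.23E-01	literature
rs4737009	8	41749562	ANK1	G	0.76	-0.027	0.51	-0.010	3.11E-01	0.60	-0.011	5.03E-01	0.78	-0.001	9.42E-01	0.58	-0.008	2.59E-01	literature
rs13266634	8	118253964	SLC30A8	T	0.30	-0.019	0.47	-0.018	2.13E-02	0.43	-0.032	1.23E-02	0.23	-0.010	4.91E-01	0.42	-0.020	1.03E-03	literature
rs7072268	10	70769919	HK1	T	0.50	0.018	0.76	0.008	3.71E-01	0.71	0.004	7.75E-01	0.43	0.013	3.13E-01	0.66	0.008	1.94E-01	literature
rs7903146	10	114748339	TCF7L2	T	0.28	0.054	0.02	-0.017	5.34E-01	0.04	-0.010	7.71E-01	0.27	0.000	9.98E-01	0.19	-0.004	7.11E-01	literature
rs1387153	11	92313476	MTNR1B	T	0.28	0.028	0.47	0.004	6.56E-01	0.42	0.001	9.56E-01	0.37	0.005	7.15E-01	0.44	0.003	5.94E-01	literature
rs7998202	13	112379869	ATP11A,TUBGCP3	G	0.14	0.031	0.06	0.022	1.71E-01	0.08	0.017	4.67E-01	0.09	0.027	2.13E-01	0.08	0.022	4.93E-02	literature
rs1046896	17	78278822	FN3K	T	0.31	0.035	0.51	0.028	3.20E-04	0.46	0.022	8.05E-02	0.37	0.046	4.05E-04	0.47	0.031	2.41E-07	literature
rs855791	22	35792882	TMPRSS6	G	0.58	-0.027	0.46	-0.028	3.82E-04	0.43	-0.008	5.22E-01	0.50	-0.019	1.21E-01	0.46	-0.022	2.35E-04	literature
rs16926246	10	70763398	HK1	T	0.10	-0.089	NA	NA	NA	NA	NA	NA	0.05	0.028	3.96E-01	NA	NA	NA	literature
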