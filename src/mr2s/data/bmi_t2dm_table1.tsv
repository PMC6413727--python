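snp	chr	gene	bp	beta_bmi	se_bmi	p_bmi	beta_t2dm	se_t2dm	p_t2dm
rs977747	1	TAL1(N) *TAL1*(N)	47457264	0.017	0.003	2.18E-08	-0.010	0.020	0.63
rs657452	1	AGBL4(N)	49362434	0.023	0.003	5.48E-13	-0.010	0.020	0.45
rs3101336	1	NEGR1(B,C,D,N)	72523773	0.032	0.003	2.66E-26	0.010	0.020	0.66
rs12401738	1	FUBP1(N); USP33(D)	78219349	0.02	0.003	1.15E-10	0.000	0.020	0.86
rs11165643	1	PTBP2(D,N)	96696685	0.022	0.003	2.07E-12	0.030	0.019	0.11
rs543874	1	SEC16B(N)	176156103	0.05	0.004	2.62E-35	0.039	0.019	0.093
rs2820292	1	NAV1(N)	200050910	0.018	0.003	1.83E-10	-0.010	0.020	0.45
rs10182181	2	NCOA1(B)	25003800	0.031	0.003	8.78E-24	-0.020	0.015	0.34
rs1016287	2	LINC01122(N)	59,159,129	0.0229	0.0034	2.25E-11	0.030	0.019	0.17
rs2121279	2	LRP1B(N)	142759755	0.024	0.004	2.31E-08	0.030	0.024	0.18
rs1460676	2	FIGN(N)	164275935	0.021	0.004	4.98E-08	0.020	0.024	0.49
rs1528435	15	UBE2E3(N)	65864222	0.018	0.003	1.20E-08	0.020	0.020	0.21
rs17203016	2	CREB1(B,N); KLF7(B)	207963763	0.021	0.004	3.41E-08	0.020	0.024	0.45
rs7599312	2	ERBB4(D,N)	213121476	0.021	0.003	1.17E-10	0.020	0.015	0.4
rs492400	2	PLCD4(B,Q); CYP27A1(B); USP37(N); TTLL4(M,Q); STK36(B,M); ZNF142(M); RQCD1(Q)	219057996	0.015	0.003	6.78E-09	-0.010	0.015	0.54
rs6804842	3	RARB(B)	25081441	0.018	0.003	2.48E-09	0.020	0.020	0.21
rs2365389	3	FHIT(N	61211502	0.02	0.003	1.63E-10	-0.010	0.015	0.7
rs13078960	3	CADM2(D,N)	85890280	0.029	0.004	1.74E-14	0.020	0.020	0.44
rs16851483	3	RASA2(N)	142758126	0.048	0.008	3.55E-10	-0.010	0.034	0.82
rs13107325	4	SLC39A8(M,N,Q)	103407732	0.047	0.007	1.83E-12	0.039	0.042	0.38
rs11727676	4	HHIP(B,N)	145878514	0.037	0.006	2.55E-08	-0.077	0.045	0.12
rs205262	6	C6orf106(N); SNRPC(Q)	34671142	0.021	0.003	1.75E-10	0.000	0.020	0.97
rs2033529	6	TDRG1(N); LRFN2(D)	40456631	0.018	0.003	1.39E-08	0.020	0.020	0.32
rs2207139	6	TFAP2B(B,N)	50953449	0.045	0.004	4.13E-29	0.039	0.024	0.14
rs9400239	6	FOXO3(B,N); HSS00296402(Q)	109084356	0.017	0.003	1.61E-08	0.010	0.020	0.62
rs13201877	6	IFNGR1(N); OLIG3(G)	137717234	0.024	0.004	4.29E-08	0.030	0.029	0.23
rs13191362	6	PARK2(B,D,N)	162953340	0.029	0.005	7.34E-09	0.020	0.029	0.4
rs1167827	7	HIP1(B,N); PMS2L3(B,Q); PMS2P5(Q); WBSCR16(Q)	75001105	0.02	0.003	6.33E-10	–	0.024	0.24
rs2245368	7	PMS2L11(N)	76,446,079	0.0317	0.0057	3.19E-08	0.049	0.033	0.15
rs6465468	7	ASB4(B,N)	95007450	0.016	0.003	4.98E-08	-0.030	0.019	0.23
rs2033732	8	RALYL(D,N)	85242264	0.018	0.003	4.89E-08	-0.010	0.020	0.63
rs4740619	9	C9orf93(C,M,N)	15624326	0.017	0.003	4.56E-09	0.020	0.020	0.29
rs10968576	9	LINGO2(D,N)	28404339	0.025	0.003	6.61E-14	0.000	0.020	1
rs6477694	9	EPB41L4B(N); C9orf4(D)	110972163	0.017	0.003	2.67E-08	0.010	0.020	0.42
rs1928295	9	TLR4(B,N)	119418304	0.018	0.003	7.91E-10	0.030	0.015	0.12
rs10733682	9	LMX1B(B,N)	128500735	0.019	0.003	1.83E-08	0.030	0.019	0.057
rs7899106	10	GRID1(B,N)	87400884	0.038	0.007	2.96E-08	-0.020	0.034	0.67
rs11030104	11	BDAF(B,M,N)	27641093	0.042	0.004	5.56E-28	0.010	0.025	0.49
rs12286929	11	CADM1(N)	114527614	0.021	0.003	1.31E-12	0.010	0.020	0.5
rs11057405	12	CLIP1(N)	121347850	0.03	0.005	2.02E-08	-0.095	0.044	0.055
rs10132280	14	STXBP6(N)	24998019	0.022	0.003	1.14E-11	0.030	0.019	0.12
rs3736485	15	SCG3(B,D); DMXL2(M,N)	49535902	0.016	0.003	7.41E-09	0.020	0.015	0.29
rs16951275	2	M4P2K5(B,D,N); LBXCOR1(M)	181259207	0.03	0.004	1.91E-17	0.030	0.019	0.21
rs758747	16	NLRC3(N)	3567359	0.023	0.004	7.47E-10	0.000	0.025	0.97
rs3888190	16	ATXN2L(Q); SBK1(Q,D); SULT1A2(Q); TUFM(Q)	28796987	0.031	0.003	3.14E-23	0.010	0.015	0.77
rs1000940	17	RABEP1(N)	5223976	0.018	0.003	1.28E-08	0.010	0.025	0.49
rs1808579	18	NPC1(B,G,M,Q); C18orf8(N,Q)	19358886	0.016	0.003	4.17E-08	0.030	0.019	0.13
rs7239883	18	LOC284260(N); RIT2(B,D)	38401669	0.015	0.003	1.51E-08	0.020	0.015	0.34
rs29941	14	KCTD15(N)	78969207	0.018	0.003	2.41E-08	0.000	0.020	0.92
rs2287019	19	QPCTL(N); GIPR(B,M)	50894012	0.035	0.004	4.59E-18	-0.030	0.029	0.33
rs6091540	20	ZFP64(N)	50521269	0.019	0.003	2.15E-11	0.010	0.020	0.8
rs2836754	21	ETS2(N)	39213610	0.017	0.003	1.61E-08	-0.020	0.020	0.18
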