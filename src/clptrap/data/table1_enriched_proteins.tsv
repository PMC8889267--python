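accession	name	function	n_bioreps_trap_observed	total_adjspc_all	total_adjspc_wt	total_adjspc_trap	avg_ratio	p_value
ATCG00190.1	rpoB RNA polymerase (PEP) beta	DNA-RNA	3	35	3	32	12.6	0.01500
ATCG00180.1	rpoC1 RNA polymerase (PEP) beta	DNA-RNA	3	41	3	38	16.4	0.00820
AT5G46580.1	pentatricopeptide repeat (PPR) protein SOT1	DNA-RNA	3	82	15	67	4.0	0.02370
AT5G26742.1	DEAD box RNA helicase (RH3)	DNA-RNA	3	244	21	223	12.6	0.00010
AT4G36390.1	tRNA/rRNA methyltransferase	DNA-RNA	3	29	2	27	14.9	0.01470
AT4G31210.1	DNA-directed topoisomerase	DNA-RNA	3	30	4	26	9.2	0.02230
AT4G09730.1	DEAD box RNA helicase RH39	DNA-RNA	3	27	1	26	26.4	0.01710
AT3G48500.1	nucleoid protein pTAC10	DNA-RNA	3	54	6	48	10.8	0.00770
AT3G10270.1	DNA gyrase B1	DNA-RNA	3	24	4	20	6.7	0.04090
AT3G04260.1	SAP domain protein pTAC3	DNA-RNA	3	58	5	53	9.9	0.00910
AT3G02060.1	DEAD/DEAH box helicase	DNA-RNA	3	18	0	18	13.9	0.02500
AT2G39670.1	tRNA/rRNA methyltransferase	DNA-RNA	2	21	0	21	16.5	0.01910
AT1G74850.1	pentatricopeptide repeat pTAC2	DNA-RNA	3	25	0	25	19.7	0.01400
AT1G30680.1	DNA primase-helicase	DNA-RNA	3	37	2	35	17.1	0.01060
AT1G02150.1	pentatricopeptide repeat (PPR) protein	DNA-RNA	3	123	26	97	3.7	0.01700
AT5G67030.1	zeaxanthin epoxidase (ZEP)	metabolism	3	62	13	49	3.2	0.04950
AT5G64840.1	ABC transporter family protein (ATGCN5)	metabolism	3	49	2	47	15.6	0.00750
AT5G60600.1	4-hydroxy-3-methylbutyl diphosphate synthase (HDS)	metabolism	3	199	34	165	4.8	0.00400
AT5G52920.1	pyruvate kinase-2	metabolism	3	31	5	26	5.7	0.04290
AT5G45930.1	Mg-protoporphyrin IX chelatase CHLI-2	metabolism	3	24	3	21	8.3	0.03680
AT5G13110.1	glucose-6-phosphate dehydrogenase 2 (G6PD2)	metabolism	3	26	3	22	7.2	0.04170
AT4G30720.1	pigment defective 327 (PDE327)	metabolism	3	43	9	34	4.1	0.05010
AT4G22240.1	fibrillin 1b (FBN1b)	metabolism	3	32	0	32	25.1	0.00790
AT4G21990.1	5'-adenylylsulfate reductase-3 (APR3)	metabolism	3	81	4	77	24.7	0.00120
AT4G15560.1	1-deoxy-D-xylulose 5-phosphate synthase (DXS1)	metabolism	3	66	8	58	6.4	0.01250
AT4G11570.1	ARPP phosphatase cpFHy2 or PYRP2	metabolism	3	84	0	84	68.9	0.00040
AT4G04610.1	5'-adenylylsulfate reductase-1 (APR1)	metabolism	3	218	24	194	8.5	0.00040
AT4G04020.1	fibrillin 1a (FBN1a)	metabolism	3	74	14	60	3.7	0.02860
AT3G44720.1	arogenate dehydratase 4 (ADT4)	metabolism	3	34	1	33	50.3	0.00730
AT3G21200.1	GluTR binding protein (GBP or PGR7)	metabolism	3	24	3	21	5.2	0.06020
AT3G10970.1	PYRP2-related HAD hydrolase	metabolism	2	54	0	54	43.1	0.00200
AT3G07630.1	arogenate dehydratase 2 (ADT2)	metabolism	3	25	4	21	4.3	0.07420
AT2G44530.1	ribose-phosphate pyrophosphokinase	metabolism	3	38	5	33	4.8	0.04410
AT2G35390.1	ribose-phosphate pyrophosphokinase 1 (PRSI)	metabolism	3	28	3	25	8.5	0.03000
AT2G29630.1	thiamine biosynthesis (thiC family)	metabolism	3	40	5	35	5.7	0.02780
AT1G62180.1	5'-adenylylsulfate reductase-2 (APR2)	metabolism	3	270	26	245	10.2	0.00010
AT1G36180.1	acetyl-CoA carboxylase ACC2	metabolism	3	147	0	147	137.4	0.00000
AT5G51110.1	Rubisco assembly factor 2 (RAF2)	proteostasis	2	33	8	25	3.4	0.09030
AT5G51070.1	CLPD	proteostasis	3	575	111	464	3.8	0.00040
AT5G42390.1	stromal processing peptidase (SPP)	proteostasis	2	63	10	53	5.6	0.02050
AT5G20720.1	CPN20	proteostasis	3	89	9	80	10.3	0.00230
AT4G25370.1	CLPT1	proteostasis	3	24	0	24	18.3	0.01590
AT4G12060.1	CLPT2	proteostasis	3	38	6	32	5.4	0.03320
AT3G48870.1	CLPC2	proteostasis	3	1527	170	1356	66.3	0.00000
AT2G44650.1	CPN10-1	proteostasis	3	19	0	19	17.3	0.01810
AT2G03390.1	CLPF (adaptor)	proteostasis	3	76	10	66	5.6	0.01250
AT1G35340.1	LON-domain protein 2 (LON-like2)	proteostasis	3	25	3	22	7.9	0.03690
AT5G66050.1	UVR4 (DUF151 and UVR domain)	unknown	3	60	0	60	46.7	0.00150
AT5G24060.1	HugZ-1	unknown	3	98	0	98	83.5	0.00020
AT4G33630.1	Executer 1 (EXE1)	unknown	3	194	0	194	178.5	0.00000
AT3G29240.1	DUF179-3	unknown	3	427	73	354	4.6	0.00050
AT3G17800.1	DUF760-5	unknown	3	180	1	179	142.2	0.00000
AT2G14910.1	DUF760-4	unknown	3	103	2	101	43.0	0.00040
AT1G75380.1	UVR2 (DUF151 and UVR domain)	unknown	2	34	1	33	28.4	0.01070
AT1G48450.1	DUF760-2	unknown	3	600	16	584	32.1	0.00000
AT1G32160.1	DUF760-1	unknown	2	23	4	19	4.4	0.08430
AT1G27510.1	Executer 2 (EXE2)	unknown	3	233	0	233	215.7	0.00000
AT1G23180.1	armadillo repeat protein (ARM)	unknown	3	78	4	74	16.6	0.00220
AT1G19660.1	UVR3 (DUF151 and UVR domain)	unknown	2	20	0	20	16.1	0.01990
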