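# Consensus modifier-gene table (52 genes) with per-gene maximal
# meta-analysis p-value, direction, and multi-tissue mean effects
# (individual-level beta; summary-level z). Section A genes lie in
# regions of known GWAS association, section B elsewhere. The tss
# column is a SYNTHETIC stand-in position consistent with the
# section labels (A within 1 Mb of a locus anchor, B not); real
# coordinates are not shipped.
gene	gene_type	chrom	max_p	direction	mean_beta	mean_z	section	tss
MUC20	protein_coding	chr3	0.0081	protective	0.014	2.44	A	99400000
MUC4	protein_coding	chr3	0.0059	protective	0.011	2.1	A	99800000
SDHAP1	pseudogene	chr3	0.00023	harmful	-0.021	-4.1	A	100200000
AC069213.1	pseudogene	chr3	0.0049	harmful	-0.012	-2.06	A	100600000
AC026740.1	protein_coding	chr5	0.00031	protective	0.01	2.97	A	100000
AHRR	protein_coding	chr5	0.0037	protective	0.003	0.97	A	220000
BRD9	protein_coding	chr5	0.00013	harmful	-0.002	-3.95	A	340000
C5orf55	protein_coding	chr5	4.7e-05	harmful	-0.02	-3.95	A	460000
CCDC127	protein_coding	chr5	0.0058	harmful	-0.006	-1.83	A	580000
CEP72	protein_coding	chr5	1.8e-09	protective	0.019	5.66	A	700000
CTD-2083E4.5	pseudogene	chr5	0.0063	harmful	-0.007	-1.8	A	820000
CTD-2228K2.5	protein_coding	chr5	1.6e-05	harmful	-0.01	-2.99	A	940000
EXOC3	protein_coding	chr5	3.5e-06	protective	0.028	4.86	A	1060000
TPPP	protein_coding	chr5	1e-07	harmful	-0.012	-4.08	A	1180000
ZDHHC11	protein_coding	chr5	9.4e-06	protective	0.005	4.41	A	1300000
ZDHHC11B	protein_coding	chr5	0.00011	protective	0.003	4.13	A	1420000
AGER	protein_coding	chr6	0.0065	harmful	-0.007	-2.39	A	31200000
CYP21A2	protein_coding	chr6	0.0026	harmful	-0.01	-2.39	A	31400000
HLA-DQA1	protein_coding	chr6	0.0001	protective	0.026	3.84	A	31600000
HLA-DQA2	protein_coding	chr6	0.00025	harmful	-0.049	-4.76	A	31800000
HLA-DQB1	protein_coding	chr6	0.00039	protective	0.04	3.48	A	32000000
HLA-DRB1	protein_coding	chr6	5.1e-05	protective	0.024	3.61	A	32200000
HLA-DRB6	pseudogene	chr6	1.1e-05	harmful	-0.052	-4.67	A	32400000
HLA-DRB9	pseudogene	chr6	0.0018	harmful	-0.017	-2.77	A	32600000
PRRT1	protein_coding	chr6	0.00053	harmful	-0.01	-2.39	A	32800000
PDHX	protein_coding	chr11	0.0031	harmful	-0.011	-2.01	A	34600000
CHP2	protein_coding	chr16	0.0019	protective	-0.002	0.74	A	28200000
PRKCB	protein_coding	chr16	0.0096	harmful	-0.002	-0.1	A	28800000
MYCL	protein_coding	chr1	0.005	protective	0.006	2.28	B	5000000
AJ239322.1	lincRNA	chr2	0.0081	protective	0.007	2.74	B	5000000
PLA2R1	protein_coding	chr2	0.0088	harmful	-0.008	-2.11	B	8000000
RP11-496H1.2	lincRNA	chr3	0.008	harmful	-0.004	-2.43	B	5000000
OSTN	protein_coding	chr3	0.0095	protective	0.005	1.82	B	8000000
SLITRK3	protein_coding	chr3	0.0081	protective	0.002	2.32	B	11000000
TAPT1	protein_coding	chr4	0.0087	harmful	-0.0004	-0.36	B	5000000
DSE	protein_coding	chr6	0.00092	harmful	-0.006	-1.51	B	5000000
CDSN	protein_coding	chr6	0.00061	harmful	-0.015	-3.75	B	8000000
HLA-S	pseudogene	chr6	0.0059	harmful	-0.019	-2.5	B	11000000
HEATR2	protein_coding	chr7	0.0058	protective	0.011	2.21	B	5000000
MET	protein_coding	chr7	0.0072	harmful	-0.006	-0.92	B	8000000
RP11-56A10.1	pseudogene	chr8	0.0074	harmful	-0.007	-3.16	B	5000000
C9orf16	protein_coding	chr9	0.0096	protective	-0.0001	0.34	B	5000000
SMTNL1	protein_coding	chr11	0.0082	protective	0.022	3.08	B	5000000
OASL	protein_coding	chr12	0.0046	harmful	-0.004	-1.8	B	5000000
TFCP2	protein_coding	chr12	0.0027	harmful	-0.003	-2.56	B	8000000
TMEM30B	protein_coding	chr14	0.0099	harmful	-0.002	-0.61	B	5000000
MTFMT	protein_coding	chr15	0.0056	harmful	-0.003	-1.61	B	5000000
RP11-491F9.8	lincRNA	chr16	0.0075	harmful	-0.015	-3.25	B	5000000
MYL4	protein_coding	chr17	0.0087	harmful	-0.005	-2.69	B	5000000
HDHD2	protein_coding	chr18	0.0039	protective	0.003	1.51	B	5000000
DESI1	protein_coding	chr22	0.0026	harmful	-0.009	-2.84	B	5000000
TMPRSS6	protein_coding	chr22	0.0036	harmful	-0.0004	-0.36	B	8000000
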