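gene_id	gene_name	treatment	pc_logfc	pc_pvalue	sm_logfc	sm_pvalue	pc_higher	sm_higher	repeated
SPSB3	splA/ryanodine receptor domain and SOCS box protein 3	24 h	1.41	5.77e-05	-1.12	3.05e-04	HW	C	1
HPX	Hemopexin	24 h	-2.02	1.54e-05	2.60	3.94e-06	LW	O	0
PTP4A2	Protein tyrosine phosphatase 4A2	24 h	-1.54	1.56e-07	-1.19	1.70e-05	LW	C	0
ADM2	Adrenomedullin 2	24 h	2.04	3.23e-08	-2.67	4.68e-08	HW	C	1
TMEM67	Transmembrane protein 67	24 h	-1.35	2.00e-06	1.45	9.88e-05	LW	O	0
CYTL1	Cytokine like 1	48 h	-1.97	4.78e-06	-2.33	3.80e-08	LW	C	0
FGL1	Fibrinogen like 1	48 h	-0.97	2.00e-04	0.83	1.51e-02	LW	O	0
RCN1	Reticulocalbin 1	48 h	1.15	6.08e-05	-1.39	4.68e-03	HW	C	0
MARS1	Methionyl-tRNA synthetase 1	48 h	1.22	2.35e-04	-1.00	2.42e-05	HW	C	0
ESCO2	Establ. of sister chromatid cohesion N-acetyltransferase 2	48 h	1.18	3.40e-04	-1.28	1.95e-03	HW	C	0
ARHGEF3	Rho guanine nucleotide exchange factor 3	48 h	-1.36	8.41e-05	-0.97	3.59e-05	LW	C	0
PKLR	Pyruvate kinase L/R	48 h	3.80	2.40e-12	-0.83	9.02e-03	HW	C	1
FARSA	Phenylalanyl-tRNA synthetase subunit alpha	48 h	1.47	1.33e-04	-1.66	2.92e-09	HW	C	0
CARS1	Cysteinyl-tRNA synthetase 1	48 h	1.15	8.07e-05	-1.29	9.68e-08	HW	C	0
SPSB3	splA/ryanodine receptor domain and SOCS box protein 3	48 h	2.05	3.89e-05	-1.12	3.05e-04	HW	C	1
FCHSD1	FCH and double SH3 domains 1	48 h	-0.82	4.34e-04	1.40	6.91e-05	LW	O	0
PMM1	Phosphomannomutase 1	48 h	0.99	2.25e-04	1.57	9.36e-05	HW	O	0
ADM2	Adrenomedullin 2	48 h	1.63	1.53e-04	-2.67	4.68e-08	HW	C	1
GP2	Glycoprotein 2	48 h	-1.47	6.76e-06	1.35	1.09e-03	LW	O	0
GART	Phosphoribosylglycinamide formyltransferase	48 h	0.97	3.65e-04	-1.01	7.71e-03	HW	C	0
DHCR24	24-dehydrocholestrol reductase	48 h	3.39	4.81e-09	0.91	4.60e-03	HW	O	1
TM7SF2	Transmembrane 7 superfamily member 2	48 h	1.51	1.49e-04	1.78	1.40e-07	HW	O	0
CYP51A1	Cytochrome P450 family 51 subfamily A member 1	48 h	3.59	3.79e-15	1.97	4.01e-05	HW	O	1
TYR	Tyrosinase	48 h	1.10	1.54e-05	0.91	3.33e-03	HW	O	0
SCD	Stearoyl-CoA desaturase	48 h	1.96	8.41e-05	-1.15	5.54e-03	HW	C	0
NARS1	Asparaginyl-tRNA synthetase 1	48 h	1.57	7.01e-06	-0.93	1.02e-03	HW	C	0
MSMO1	Methylsterol monooxygenase 1	48 h	3.13	3.00e-09	1.95	8.59e-04	HW	O	1
ACSS2	Acyl-CoA synthetase short chain family member 2	48 h	2.14	8.51e-05	2.08	4.99e-11	HW	O	1
TP53RK	TP53 regulating kinase	48 h	1.78	4.21e-07	-0.81	4.36e-03	HW	C	0
PHGDH	Phosphoglycerate dehydrogenase	48 h	1.62	2.55e-07	-2.32	4.66e-10	HW	C	0
C9ORF64	Q-nucleotide N-glycosylase 1	48 h	2.74	3.11e-04	1.06	2.74e-03	HW	O	0
PSAT1	Phosphoserine aminotransferase 1	48 h	1.92	1.66e-06	0.93	7.32e-03	HW	O	0
CYP4F22	Cytochrome P450 family 4 subfamily F member 22	48 h	2.01	1.22e-09	0.92	2.41e-03	HW	O	0
IPO4	Importin 4	48 h	1.19	3.70e-04	-1.04	3.51e-04	HW	C	0
MAD2L1BP	MAD2L1 binding protein	48 h	1.94	4.32e-06	-1.55	4.14e-03	HW	C	0
ACAT2	Acetyl-CoA acetyltransferase 2	48 h	1.25	2.45e-04	0.92	7.02e-03	HW	O	0
STOML2	Stomatin like 2	48 h	1.85	1.44e-05	-1.36	1.67e-06	HW	C	0
FEN1	Flap structure-specific endonuclease 1	48 h	1.20	3.67e-04	-0.95	6.95e-03	HW	C	0
CRYGD	Crystallin gamma D	48 h	1.57	7.35e-05	0.81	1.12e-02	HW	O	0
ADK	Adenosine kinase	48 h	1.46	7.77e-05	-0.78	1.64e-02	HW	C	0
PKLR	Pyruvate kinase L/R	72 h	3.00	4.50e-07	-0.83	9.02e-03	HW	C	1
TMEM97	Transmembrane protein 97	72 h	1.23	2.22e-04	1.50	2.96e-06	HW	O	0
CALU	Calumenin	72 h	-1.94	1.88e-04	-0.92	1.68e-02	LW	C	0
HSD3B7	Hydroxy-delta-5-steroid dehydrogenase	72 h	1.52	2.76e-04	1.66	8.26e-05	HW	O	0
AOC1	Amine oxidase copper containing 1	72 h	-2.05	8.82e-06	1.56	3.35e-05	LW	O	0
CYP51A1	Cytochrome P450 family 51 subfamily A member 1	72 h	3.03	5.33e-10	1.97	4.01e-05	HW	O	1
DHCR24	24-dehydrocholestrol reductase	72 h	2.84	5.94e-07	0.91	4.60e-03	HW	O	1
MSMO1	Methylsterol monooxygenase 1	72 h	2.61	4.18e-07	1.95	8.59e-04	HW	O	1
PISD	Phosphatidylserine decarboxylase	72 h	1.72	2.20e-04	-1.02	9.57e-05	HW	C	0
ACSS2	Acyl-CoA synthetase short chain family member 2	72 h	2.29	4.74e-05	2.08	4.99e-11	HW	O	1
MARCHF8	Membrane associated ring-CH-type finger 8	72 h	4.59	5.64e-08	1.37	4.23e-04	HW	O	0
HMGCR	3-hydroxy-3-methylglutaryl-CoA reductase	72 h	2.00	1.17e-04	1.43	1.80e-05	HW	O	0
ATL2	Atlastin GTPase 2	72 h	3.45	4.02e-06	0.62	8.75e-03	HW	O	0
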