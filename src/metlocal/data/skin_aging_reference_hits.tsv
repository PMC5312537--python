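gene	gene_name	S	p_locality	rho_age	p_age	log2fc	adj_p
ALDH4A1	aldehyde dehydrogenase 4 family, member A1	0.25	1e-04	-0.33	0.026	-0.26	0.006
ODC1	ornithine decarboxylase 1	0.26	2e-04	-0.26	0.076	-0.30	0.085
GALNT6	polypeptide N-acetylgalactosaminyltransferase 6	0.22	4e-04	0.38	0.01	0.30	0.112
TARS2	threonyl-tRNA synthetase 2, mitochondrial (putative)	0.31	7e-04	0.55	7e-05	0.45	7e-05
BCKDHA	branched chain keto acid dehydrogenase E1, alpha polypeptide	0.21	0.002	0.34	0.022	0.18	0.026
ALDOA	aldolase A, fructose-bisphosphate	0.24	0.003	0.57	3e-05	0.24	0.002
TARS	threonyl-tRNA synthetase	0.29	0.003	-0.54	1e-04	-0.75	6e-06
YARS2	tyrosyl-tRNA synthetase 2, mitochondrial	0.28	0.006	-0.39	0.007	-0.27	0.011
CYP51A1	cytochrome P450, family 51, subfamily A, polypeptide 1	0.19	0.008	-0.40	0.005	-0.20	0.012
ALAD	aminolevulinate dehydratase	0.24	0.008	0.19	0.204	0.22	0.061
IL4I1	interleukin 4 induced 1	0.21	0.014	-0.16	0.297	-0.58	0.052
FBP1	fructose-1,6-bisphosphatase 1	0.27	0.016	0.34	0.022	0.22	0.094
GATM	glycine amidinotransferase (L-arginine:glycine amidinotransferase)	0.26	0.017	0.37	0.012	0.29	0.019
YARS	tyrosyl-tRNA synthetase	0.27	0.02	-0.48	8e-04	-0.54	6e-04
GART	phosphoribosylglycinamide formyltransferase, phosphoribosylglycinamide synthetase, phosphoribosylaminoimidazole synthetase	0.28	0.021	-0.35	0.019	-0.39	0.006
PRDX6	peroxiredoxin 6	0.24	0.021	0.36	0.015	0.14	0.056
AGA	aspartylglucosaminidase	0.18	0.032	0.25	0.101	0.15	0.077
TST	thiosulfate sulfurtransferase (rhodanese)	0.24	0.034	0.31	0.039	0.31	0.041
ACP5	acid phosphatase 5, tartrate resistant	0.26	0.038	0.31	0.036	0.36	0.007
IARS	isoleucyl-tRNA synthetase	0.28	0.039	-0.40	0.006	-0.44	0.002
NDUFV2	NADH dehydrogenase (ubiquinone) flavoprotein 2, 24kDa	0.22	0.041	0.26	0.077	0.13	0.062
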