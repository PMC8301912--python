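accession	description	gene	fc	p
P56202	Cathepsin W	CTSW	1.53	0.005
P13747	HLA class I histocompatibility antigen, alpha chain E	HLA-E	1.34	0.010
Q6IAA8	Ragulator complex protein LAMTOR1	LAMTOR1	1.32	0.031
Q9BYM8	RanBP-type and C3HC4-type zinc finger-containing protein 1	RBCK1	1.22	0.025
Q9BSJ2	Gamma-tubulin complex component 2	TUBGCP2	1.20	0.022
Q9NZ63	Telomere length and silencing protein 1 homolog	C9orf78	1.19	0.010
O75718	Cartilage-associated protein	CRTAP	1.17	0.045
Q9NYM9	BET1-like protein	BET1L	1.17	0.018
Q96DM3	Regulator of MON1-CCZ1 complex	RMC1	1.15	0.024
O95372	Acyl-protein thioesterase 2	LYPLA2	1.14	0.036
O15427	Monocarboxylate transporter 4	SLC16A3	1.13	0.028
Q8TCD5	5'(3')-deoxyribonucleotidase, cytosolic type	NT5C	1.12	0.043
P49459	Ubiquitin-conjugating enzyme E2 A	UBE2A	1.12	0.016
Q8NB16	Mixed lineage kinase domain-like protein	MLKL	0.89	0.049
Q6NUK1	Calcium-binding mitochondrial carrier protein SCaMC-1	SLC25A24	0.88	0.026
Q8NCN5	Pyruvate dehydrogenase phosphatase regulatory subunit, mitochondrial	PDPR	0.87	0.015
P56381	ATP synthase subunit epsilon, mitochondrial	ATP5F1E	0.86	0.030
Q9BZ23	Pantothenate kinase 2, mitochondrial	PANK2	0.85	0.017
Q14657	EKC/KEOPS complex subunit LAGE3	LAGE3	0.84	0.023
O95497	Pantetheinase	VNN1	0.75	0.028
P13645	Keratin, type I cytoskeletal 10	KRT10	0.66	0.036
Q7Z3D6	D-glutamate cyclase, mitochondrial	DGLUCY	0.60	0.030
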