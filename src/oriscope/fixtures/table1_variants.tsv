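lineage	gene	annotation	mutation	allele_frequency	description
WT-1	mrdB	R69H (CGC→CAC)	C→T	100	Cell wall shape-determining protein
WT-1	pyrE-rph		Δ82 bp	100	Orotate phosphoribosyltransferase-ribonuclease PH (defective); enzyme; degradation of RNA; RNase PH
WT-1	rpoB	A1055V (GCG→GTG)	C→T	100	RNA polymerase, beta subunit
WT-2	cysE	S224A (TCC→GCC)	A→C	100	Serine acetyltransferase
WT-2	rpoC	R1075C (CGT→TGT)	C→T	100	RNA polymerase, beta prime subunit
WT-3	rlmH	S121* (TCG→TAG)	G→T	100	23S rRNA m(3)Psi1915 pseudouridine methyltransferase, SAM dependent
WT-3	ydhZ-pykF	Intergenic (−284/−273)	Δ1 bp	100	Uncharacterized protein/pyruvate kinase I
WT-3	ybcL		IS2 (+) +5 bp	87.90	Inactive polymorphonuclear leukocyte migration suppressor; DLP12 prophage; UPF0098 family secreted protein
O3-1	pykF	R385L (CGC→CTC)	G→T	100	Pyruvate kinase I
O3-1	gtrB	S267L (TCA→TTA)	C→T	100	CPS-53 (KpLE1) prophage; bactoprenol glucosyl transferase
O3-1	rpoB	I524M (ATT→ATG)	T→G	100	RNA polymerase, beta subunit
O3-1	spoT	Y14D (TAC→GAC)	T→G	91.00	Bifunctional (p)ppGpp synthetase II/guanosine 3',5'-bis(pyrophosphate) 3'-pyrophosphohydrolase
O3-2	yeiH	I137F (ATC→TTC)	A→T	100	UPF0324 family inner membrane protein
O3-2	ptsP	Q340* (CAG→TAG)	G→A	100	PEP protein phosphotransferase enzyme I; GAF domain containing protein
O3-2	nusA	Coding (1457/1488 nt)	+G	100	Transcription termination/antitermination L factor
O3-2	pyrE-rph	Intergenic (−33/+33)	Δ1 bp	100	Orotate phosphoribosyltransferase/ribonuclease PH (defective); enzyme; degradation of RNA; RNase PH
O3-2	nagA	Coding (422/1149 nt)	Δ1 bp	51.60	N-Acetylglucosamine-6-phosphate deacetylase
O3-3	ptsP	L111* (TTA→TGA)	A→C	100	PEP protein phosphotransferase enzyme I; GAF domain-containing protein
O3-3	mreB	A82S (GCC→TCC)	C→A	100	Cell wall structural complex MreBCD, actin-like component MreB
O3-3	pyrE-rph		Δ82 bp	100	Orotate phosphoribosyltransferase/ribonuclease PH (defective); enzyme; degradation of RNA; RNase PH
O3-3	ydcK	Coding (299/981 nt)	Δ1 bp	68.90	Uncharacterized protein
O3-3	ydbA	Pseudogene (21–29/2513 nt)	IS1 (+) +9 bp	66.70	Pseudogene, autotransporter homolog; interrupted by IS2 and IS30
O3-3	cyaA	R160L (CGC→CTC)	G→T	64.40	Adenylate cyclase
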