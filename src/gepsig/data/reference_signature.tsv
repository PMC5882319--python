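gene_symbol	cytoband	description
ANGPT2	8p23.1	angiopoietin 2
C1QA	1p36.12	complement component 1, q subcomponent, A chain
CAV2	7q31.2	caveolin 2
CDKN1A	6p21.2	cyclin-dependent kinase inhibitor 1A (p21, Cip1)
DKK3	11p15.3	dickkopf WNT signaling pathway inhibitor 3
EDNRA	4q31.22	endothelin receptor type A
EXT1	8q24.11	exostosin glycosyltransferase 1
FGF9	13q12.11	fibroblast growth factor 9
FMO2	1q24.3	flavin containing monooxygenase 2
LAMP5	20p12.2	lysosomal-associated membrane protein family, member 5
MLPH	2q37.3	melanophilin
PHLDA2	11p15.4	pleckstrin homology-like domain, family A, member 2
RHOBTB3	5q15	Rho-related, broad-complex, tramtrack and bric-a-brac domain containing 3
RUNDC3B	7q21.12	RUN domain containing 3B
SCG2	2q36.1	secretogranin II
SEMA3C	7q21.11	sema domain, immunoglobulin domain, short basic domain, secreted, (semaphorin) 3C
SLC1A3	5p13.2	solute carrier family 1 (glial high affinity glutamate transporter), member 3
TSPAN7	Xp11.4	tetraspanin 7
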