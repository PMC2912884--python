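COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC	verapamil
Cc1ccccc1	toluene
COc1ccccc1	anisole
CCc1ccccc1	ethylbenzene
CC(=O)Nc1ccc(O)cc1	acetaminophen
CC(C)Cc1ccc(cc1)C(C)C(=O)O	ibuprofen
CCN(CC)CC(=O)Nc1c(C)cccc1C	lidocaine
CC(C)NCC(O)COc1cccc2ccccc12	propranolol
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
COC(=O)c1ccccc1	methyl-benzoate
CCOC(C)=O	ethyl-acetate
CNC(=O)c1ccccc1	n-methylbenzamide
C=Cc1ccccc1	styrene
CC(=C)C1CCC(C)=CC1	limonene
CN(C)CCOC(c1ccccc1)c2ccccc2	diphenhydramine
COCCc1ccc(OCC(O)CNC(C)C)cc1	metoprolol
COc1ccc2cc(ccc2c1)C(C)C(=O)O	naproxen
CCN(CC)CCOC(=O)c1ccc(N)cc1	procaine
CN(C)CCCN1c2ccccc2CCc2ccccc21	imipramine
CCOc1ccc(NC(=O)C)cc1	phenacetin
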