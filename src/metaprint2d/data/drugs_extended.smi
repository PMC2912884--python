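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
CC(=O)Oc1ccccc1C(=O)O	aspirin
CN1CCCC1c1cccnc1	nicotine
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1	atenolol
CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1	chlorpheniramine
CN(C)CC(c1ccc(OC)cc1)C1(O)CCCCC1	venlafaxine
CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1	fluoxetine
CC(N)COc1c(C)cccc1C	mexiletine
CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1	ketoprofen
CCOC(=O)c1ccc(N)cc1	benzocaine
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21	diazepam
CN(C)CCC=C1c2ccccc2CCc2ccccc21	amitriptyline
CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1	tolbutamide
Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F	celecoxib
NC(=O)N1c2ccccc2C=Cc2ccccc21	carbamazepine
COc1ccc2c(c1)c(CCNC(C)=O)c[nH]2	melatonin
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O	warfarin
COc1ccc(Cc2nccc3cc(OC)c(OC)cc23)cc1OC	papaverine
CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1	tamoxifen
O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1	phenytoin
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1	sulfamethoxazole
Cn1c(=O)c2[nH]cnc2n(C)c1=O	theophylline
CN1CCCCC1C(=O)Nc1c(C)cccc1C	mepivacaine
CCOC(=O)C(C)(C)Oc1ccc(Cl)cc1	clofibrate
CCCNC(=O)NS(=O)(=O)c1ccc(Cl)cc1	chlorpropamide
CC(C(=O)O)c1ccc(-c2ccccc2)c(F)c1	flurbiprofen
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC	trimethoprim
CC1=CC(=O)N(c2ccccc2)N1C	phenazone
CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1	bupropion
CN(C)CC1CCCCC1(O)c1cccc(OC)c1	tramadol
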