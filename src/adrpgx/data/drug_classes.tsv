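drug	atc	drug_class	cyp2c19_metabolised
escitalopram	N06AB10	SSRI	1
citalopram	N06AB04	SSRI	1
sertraline	N06AB06	SSRI	1
fluoxetine	N06AB03	SSRI	0
paroxetine	N06AB05	SSRI	0
duloxetine	N06AX21	SNRI_ATYP	0
venlafaxine	N06AX16	SNRI_ATYP	0
mirtazapine	N06AX11	SNRI_ATYP	0
bupropion	N06AX12	SNRI_ATYP	0
agomelatine	N06AX22	SNRI_ATYP	0
vortioxetine	N06AX26	SNRI_ATYP	0
trazodone	N06AX05	SNRI_ATYP	0
tianeptine	N06AX14	SNRI_ATYP	0
amitriptyline	N06AA09	TCA	1
clomipramine	N06AA04	TCA	0
nortriptyline	N06AA10	TCA	0
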