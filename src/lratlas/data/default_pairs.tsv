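receptor	ligand	ligand_kind	molecule	categories	source
CD9	HBEGF	protein		growth_factor_wnt	HBEGF binds tetraspanin CD9
CD9	ADAM2	protein		juxtacrine_matricellular	disintegrin ADAM2 binds CD9
ADIPOR1	ADIPOQ	protein		growth_factor_wnt	adiponectin receptor 1
ADIPOR2	ADIPOQ	protein		growth_factor_wnt	adiponectin receptor 2
ITGB1	MDK	protein		growth_factor_wnt	midkine binds integrin beta-1
SDC4	MDK	protein		growth_factor_wnt	midkine binds syndecan-4
LRP2	MDK	protein		growth_factor_wnt	midkine binds megalin/LRP2
MAGED1	NGF	protein		growth_factor_wnt	nerve growth factor receptor component
CKAP4	DKK1	protein		growth_factor_wnt	alternate DKK1 receptor
RYK	WNT5A	protein		growth_factor_wnt	WNT5A receptor RYK
PDGFRA	PDGFA	protein		growth_factor_wnt	PDGF receptor alpha
PDGFRA	PDGFB	protein		growth_factor_wnt	PDGF receptor alpha
MERTK	GAS6	protein		growth_factor_wnt	growth-arrest-specific 6 receptor
LGR4	NDP	protein		growth_factor_wnt	norrin WNT agonist receptor
ACVR2A	BMP4	protein		growth_factor_wnt	BMP4 type II receptor
ACVR2B	BMP4	protein		growth_factor_wnt	BMP4 type II receptor
ITGB1	VEGFA	protein		growth_factor_wnt	VEGFA binds integrin beta-1
SDC4	FGF2	protein		growth_factor_wnt	FGF co-receptor syndecan-4
FGFR4	FGF2	protein		growth_factor_wnt	FGF receptor 4
TGFBR1	TGFB1	protein		growth_factor_wnt	TGF-beta type I receptor
SDC2	TGFB1	protein		growth_factor_wnt	TGF-beta co-receptor syndecan-2
SDC2	HGF	protein		growth_factor_wnt	HGF co-receptor syndecan-2
CD48	IL18	protein		cytokine_chemokine	IL18 receptor CD48
ITGB1	CXCL12	protein		cytokine_chemokine	CXCL12 binds integrin beta-1
SDC4	CXCL12	protein		cytokine_chemokine	CXCL12 binds syndecan-4
AMFR	GPI	protein		cytokine_chemokine;growth_factor_wnt	autocrine motility factor receptor
SDC4	CXCL10	protein		cytokine_chemokine	CXCL10 binds syndecan-4
CSF1R	CSF1	protein		cytokine_chemokine	CSF1 receptor
SDC4	CCL5	protein		cytokine_chemokine	CCL5 binds syndecan-4
IL2RG	IL2	protein		cytokine_chemokine	common gamma chain
IL2RG	IL4	protein		cytokine_chemokine	common gamma chain
IL10RB	IL10	protein		cytokine_chemokine	IL10 receptor subunit beta
TNFRSF6B	TNFSF14	protein		cytokine_chemokine	decoy receptor 3
TNFRSF6B	TNFSF15	protein		cytokine_chemokine	decoy receptor 3
TNFRSF6B	FASLG	protein		cytokine_chemokine	decoy receptor 3
ITGB1	THBS1	protein		juxtacrine_matricellular	thrombospondin-1 integrin binding
ITGB3	THBS1	protein		juxtacrine_matricellular	thrombospondin-1 integrin binding
SDC4	THBS1	protein		juxtacrine_matricellular	thrombospondin-1 syndecan binding
CD47	THBS1	protein		juxtacrine_matricellular	thrombospondin-1 receptor CD47
CD36	THBS1	protein		juxtacrine_matricellular	thrombospondin-1 receptor CD36
ITGB1	THBS2	protein		juxtacrine_matricellular	thrombospondin-2 integrin binding
ITGB3	THBS2	protein		juxtacrine_matricellular	thrombospondin-2 integrin binding
SDC4	THBS2	protein		juxtacrine_matricellular	thrombospondin-2 syndecan binding
CD47	THBS2	protein		juxtacrine_matricellular	thrombospondin-2 receptor CD47
CD36	THBS2	protein		juxtacrine_matricellular	thrombospondin-2 receptor CD36
HHIP	IHH	protein		juxtacrine_matricellular	hedgehog-interacting protein
HHIP	DHH	protein		juxtacrine_matricellular	hedgehog-interacting protein
ITGB3	CCN1	protein		juxtacrine_matricellular	CCN1 integrin binding
ITGB1	ADAM9	protein		juxtacrine_matricellular	ADAM9 integrin binding
ITGB1	ADAM12	protein		juxtacrine_matricellular	ADAM12 integrin binding
SDC4	ADAM12	protein		juxtacrine_matricellular	ADAM12 syndecan binding
ITGB1	ADAM15	protein		juxtacrine_matricellular	ADAM15 integrin binding
ITGB3	ADAM15	protein		juxtacrine_matricellular	ADAM15 integrin binding
ITGB1	ADAM17	protein		juxtacrine_matricellular	ADAM17 integrin binding
FZD3	MYOC3	protein		juxtacrine_matricellular	secreted glycoprotein MYOC3
CXADR	JAML	protein		juxtacrine_matricellular	junction adhesion molecule-like
DCBLD2	SEMA4B	protein		juxtacrine_matricellular	semaphorin 4B receptor
ITGB1	CD14	protein		juxtacrine_matricellular	CD14 integrin binding
PTPRA	NCAM1	protein		juxtacrine_matricellular	NCAM1 receptor PTPRA
PECAM1	EFNB2	protein		juxtacrine_matricellular	ephrin B2 binds PECAM1
RPSA	LAMB1	protein		juxtacrine_matricellular	laminin receptor RPSA
CD81	C3	protein		juxtacrine_matricellular	complement C3 binds CD81
CD81	GPC3	protein		juxtacrine_matricellular	glypican-3 binds CD81
F11R	F11R	protein		juxtacrine_matricellular	homophilic tight-junction adhesion
CHRNB2	ACHE	synthesis_enzyme_proxy	acetylcholine	small_molecule	proxy assignment as published; ACHE hydrolyzes rather than synthesizes acetylcholine
PGRMC1	HSD3B1	synthesis_enzyme_proxy	progesterone	small_molecule	progesterone synthesis enzyme proxy
GPRC5C	ALDH1A2	synthesis_enzyme_proxy	retinoic acid	small_molecule	retinaldehyde dehydrogenase proxy
RXRB	ALDH1A2	synthesis_enzyme_proxy	retinoic acid	small_molecule	retinaldehyde dehydrogenase proxy
LPAR1	ENPP2	synthesis_enzyme_proxy	lysophosphatidic acid	small_molecule	autotaxin proxy
LPAR2	ENPP2	synthesis_enzyme_proxy	lysophosphatidic acid	small_molecule	autotaxin proxy
LPAR6	ENPP2	synthesis_enzyme_proxy	lysophosphatidic acid	small_molecule	autotaxin proxy
GPR34	ENPP2	synthesis_enzyme_proxy	lysophosphatidic acid	small_molecule	autotaxin proxy
HRH1	HDC	synthesis_enzyme_proxy	histamine	small_molecule	histidine decarboxylase proxy
GPBAR1	CYP7A1	synthesis_enzyme_proxy	bile acids	small_molecule	bile acid synthesis enzyme proxy
NR1H2	CH25H	synthesis_enzyme_proxy	oxysterols	small_molecule	cholesterol 25-hydroxylase proxy
ESRRG	CYP19A1	synthesis_enzyme_proxy	estradiol	small_molecule	aromatase proxy
CNR2	NAPEPLD	synthesis_enzyme_proxy	anandamide	small_molecule	endocannabinoid synthesis proxy
ADRB2	PNMT	synthesis_enzyme_proxy	catecholamines	small_molecule	epinephrine synthesis proxy
HTR2B	TPH1	synthesis_enzyme_proxy	serotonin	small_molecule	tryptophan hydroxylase proxy
PTGFR	AKR1C3	synthesis_enzyme_proxy	prostaglandin F2-alpha	small_molecule	prostaglandin F synthase proxy
GABRA5	GAD1	synthesis_enzyme_proxy	gamma-aminobutyric acid	small_molecule	glutamate decarboxylase proxy
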