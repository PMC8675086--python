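gene	alteration_class	basis	level	therapy	oncogenic
PIK3CA	missense	somatic	3B	alpelisib	yes
KRAS	missense	somatic	3B	adagrasib	yes
BRAF	missense	somatic	3B	dabrafenib+trametinib	yes
MET	any	somatic	3A	cabozantinib	yes
MTOR	any	somatic	4	everolimus	yes
VHL	plp	germline	3A	belzutifan	yes
FH	plp	germline	3B	bevacizumab+erlotinib	yes
TSC1	plp	germline	3A	everolimus	yes
TSC2	plp	germline	3A	everolimus	yes
BRCA1	plp	germline	4	olaparib	yes
BRCA2	plp	germline	4	olaparib	yes
dMMR	marker	dmmr	1	pembrolizumab	yes
SETD2	any	somatic		none	yes
VHL	any	somatic		none	yes
GNAQ	any	somatic		none	yes
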