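gene	chrom	arm	start	end
VHL	chr3	p	10000001	10020000
PBRM1	chr3	p	52000001	52140000
BAP1	chr3	p	52400001	52410000
MITF	chr3	p	69800001	70010000
SETD2	chr3	p	47050001	47210000
MLH1	chr3	p	37030001	37100000
ATR	chr3	q	142160001	142300000
PIK3CA	chr3	q	178860001	178960000
FH	chr1	q	241000001	241030000
SDHB	chr1	p	17300001	17350000
SDHC	chr1	q	161280001	161330000
ARID1A	chr1	p	27020001	27110000
MTOR	chr1	p	11160001	11330000
NRAS	chr1	p	115240001	115260000
MUTYH	chr1	p	45790001	45810000
MSH2	chr2	p	47630001	47710000
MSH6	chr2	p	48010001	48040000
KIT	chr4	q	55520001	55610000
SDHA	chr5	p	200001	260000
TERT	chr5	p	1250001	1300000
APC	chr5	q	112040001	112180000
MET	chr7	q	116300001	116440000
BRAF	chr7	q	140430001	140630000
KMT2C	chr7	q	151830001	152090000
EGFR	chr7	p	55080001	55280000
PMS2	chr7	p	6010001	6050000
NBN	chr8	q	90940001	91000000
RECQL4	chr8	q	145730001	145740000
TSC1	chr9	q	135700001	135780000
PTCH1	chr9	q	98200001	98280000
GNAQ	chr9	q	80330001	80650000
CDKN2A	chr9	p	21960001	21996000
CDKN2B	chr9	p	22000001	22010000
RET	chr10	q	43570001	43630000
ATM	chr11	q	108090001	108240000
MRE11	chr11	q	94150001	94230000
SDHD	chr11	q	111950001	111970000
INPPL1	chr11	q	71940001	71960000
KRAS	chr12	p	25350001	25410000
KMT2D	chr12	q	49410001	49460000
BRCA2	chr13	q	32880001	32980000
DICER1	chr14	q	95550001	95630000
TSHR	chr14	q	81420001	81610000
BLM	chr15	q	91260001	91360000
TSC2	chr16	p	2090001	2140000
SLX4	chr16	p	3630001	3660000
FANCA	chr16	q	89800001	89880000
CDH1	chr16	q	68770001	68870000
PALB2	chr16	p	23610001	23650000
FLCN	chr17	p	17100001	17130000
TP53	chr17	p	7560001	7590000
BRCA1	chr17	q	41190001	41280000
PPM1D	chr17	q	58670001	58740000
RAD51C	chr17	q	56770001	56810000
RAD51D	chr17	q	33420001	33450000
SMAD4	chr18	q	48550001	48610000
NOTCH3	chr19	p	15270001	15320000
STK11	chr19	p	1200001	1230000
KMT2B	chr19	q	36200001	36230000
NF2	chr22	q	29990001	30090000
CHEK2	chr22	q	29080001	29140000
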