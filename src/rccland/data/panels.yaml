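# Gene panels driving patient stratification.
# syndromic_rcc: genes of recognized hereditary RCC syndromes (VHL disease,
#   HLRCC, BHD, HPRC, BAP1-TPDS, SDH-deficient RCC, tuberous sclerosis, MITF,
#   PBRM1). ddr + other_cancer: remaining cancer-predisposition genes.
# panel: additional assay genes (somatic background / actionability targets);
#   the full membership is the union of all four lists.
syndromic_rcc:
  - VHL
  - FH
  - FLCN
  - MET
  - BAP1
  - SDHA
  - SDHB
  - SDHC
  - SDHD
  - TSC1
  - TSC2
  - MITF
  - PBRM1
ddr:
  - ATR
  - ATM
  - BLM
  - BRCA1
  - BRCA2
  - CHEK2
  - NBN
  - FANCA
  - RECQL4
  - TP53
  - SLX4
  - MRE11
  - PALB2
  - RAD51C
  - RAD51D
  - MLH1
  - MSH2
  - MSH6
  - PMS2
other_cancer:
  - DICER1
  - NF2
  - NOTCH3
  - PPM1D
  - PTCH1
  - TSHR
  - APC
  - RET
  - KIT
  - SMAD4
  - STK11
  - MUTYH
  - CDH1
panel:
  - SETD2
  - GNAQ
  - INPPL1
  - ARID1A
  - KMT2D
  - KMT2B
  - KMT2C
  - PIK3CA
  - KRAS
  - BRAF
  - MTOR
  - EGFR
  - NRAS
  - TERT
  - CDKN2A
  - CDKN2B
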