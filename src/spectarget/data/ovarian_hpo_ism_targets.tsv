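# Published worked example: ISM-predicted ruthenium-complex protein targets found
# inside the experimentally supported STRING neighbourhoods of genes annotated
# with the HPO term "Ovarian neoplasm" (HP:0100615).  One row per
# (seed network, predicted target) membership; snr is the reported cross-spectrum
# signal-to-noise of the target with the ligand.
# seed	hit	snr
MDM2	YWHAQ	11.68431
MDM2	RASSF3	9.9321
MDM2	SFN	8.26526
MDM2	UBE2E3	7.55273
MDM2	ARRB1	7.40497
MDM2	YWHAZ	6.60843
PRKN	SQSTM1	13.47355
PRKN	LIMK1	11.41166
PRKN	PSMB4	10.03283
PRKN	RHOT2	9.66055
PRKN	CDK5	7.97013
PRKN	ARRB1	7.40497
AKT1	SFN	8.26526
AKT1	HSPB1	8.24698
AKT1	SMAD3	8.13051
AKT1	EGLN1	7.58537
AKT1	YWHAZ	6.60843
SMAD4	KDM6B	14.78335
SMAD4	ACVR1B	9.87143
SMAD4	RAN	9.42564
SMAD4	SMAD3	8.13051
BRCA1	ACACA	10.60752
BRCA1	TERF2IP	9.37372
BRCA1	FAM111A	6.8921
CTNNB1	BCL9	13.42896
CTNNB1	CTNNA1	10.23149
CTNNB1	PSEN2	8.155
TP53	BAK1	16.43688
TP53	HSPB1	8.24698
TP53	BCL2L2	7.12573
MRE11	TERF2IP	9.37372
MRE11	CHAMP1	9.33687
RAD50	TERF2IP	9.37372
RAD50	CHAMP1	9.33687
TGFBR2	ACVR1B	9.87143
TGFBR2	SMAD3	8.13051
CDH1	CTNNA1	10.23149
CDKN2A	PSMC3	7.13755
CHEK2	GINS2	6.01104
DICER1	TARBP2	6.7722
EWSR1	EIF4H	10.70126
FGFR2	YWHAZ	6.60843
GATA4	FOS	11.15809
IDH1	DAZAP1	10.26606
LMNA	LMNB2	11.67122
MSH2	FBXO5	8.00492
NBN	TERF2IP	9.37372
PALB2	MORF4L2	8.04956
RAD51	RAD51AP1	14.51291
RAD51D	AMOTL2	7.63458
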