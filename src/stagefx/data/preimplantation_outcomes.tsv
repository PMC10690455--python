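# Reference preimplantation-development outcome counts for oocytes derived
# from BVSC ESC/iPSC lines (IVM/IVF/parthenogenetic activation) and in vivo
# controls. printed_percent is carried for reference only; rates are
# recomputed from numerator/denominator.
condition	transition	numerator	denominator	printed_percent
BVSC-ESC_IVM	COC_to_MII	52	235	22.1
BVSC-iPSC_IVM	COC_to_MII	722	5701	12.7
BVSC-iPSC_IVF	MII_to_2PN	52	74	70.3
invivo_IVF	MII_to_2PN	52	71	73.2
BVSC-iPSC_IVF	oocyte_to_blastocyst	14	838	1.7
BVSC-iPSC_PA	MII_to_2cell	483	722	66.9
BVSC-iPSC_PA	2cell_to_4cell	43	483	8.9
BVSC-iPSC_PA	BrUTP_negative_2cell	18	24	75.0
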