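# Synthetic subset of a mouse<->human homolog table covering common immune
# genes; one-to-one pairs only. Users supply a full table for real analyses.
mouse	human
Il1a	IL1A
Il1b	IL1B
Il1rn	IL1RN
Il18	IL18
Il33	IL33
Il2	IL2
Il4	IL4
Il6	IL6
Il7	IL7
Il9	IL9
Il10	IL10
Il12a	IL12A
Il12b	IL12B
Il13	IL13
Il15	IL15
Il17a	IL17A
Il21	IL21
Il22	IL22
Il23a	IL23A
Il27	IL27
Ebi3	EBI3
Ifna1	IFNA1
Ifnb1	IFNB1
Ifng	IFNG
Tnf	TNF
Lta	LTA
Ltb	LTB
Csf1	CSF1
Csf2	CSF2
Csf3	CSF3
Tgfb1	TGFB1
Ifngr1	IFNGR1
Ifngr2	IFNGR2
Ifnar1	IFNAR1
Ifnar2	IFNAR2
Il2ra	IL2RA
Il2rb	IL2RB
Il2rg	IL2RG
Il4ra	IL4R
Il6ra	IL6R
Il6st	IL6ST
Il7r	IL7R
Il10ra	IL10RA
Il10rb	IL10RB
Il12rb1	IL12RB1
Il12rb2	IL12RB2
Il17ra	IL17RA
Il18r1	IL18R1
Il18rap	IL18RAP
Tnfrsf1a	TNFRSF1A
Tnfrsf1b	TNFRSF1B
Stat1	STAT1
Stat2	STAT2
Stat3	STAT3
Irf1	IRF1
Irf7	IRF7
Isg15	ISG15
Ifit1	IFIT1
Ifit3	IFIT3
Mx1	MX1
Oasl2	OASL2
Rsad2	RSAD2
Usp18	USP18
Bst2	BST2
Cxcl9	CXCL9
Cxcl10	CXCL10
Ccl2	CCL2
Ccl5	CCL5
Gbp2	GBP2
Socs1	SOCS1
Socs3	SOCS3
Cd40	CD40
Cd69	CD69
Cd274	CD274
Nfkb1	NFKB1
Nfkbia	NFKBIA
Tnfaip3	TNFAIP3
Gzmb	GZMB
Prf1	PRF1
Klrg1	KLRG1
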