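# Predicted regulatory connections per TF in the signed bipartite
# heat-stress co-regulatory network (|r| >= 0.8), transcribed verbatim from
# the printed table. NOTE: the printed column labels disagree with the
# accompanying text — the text reports 687 activations and 1260 repressions,
# while the column printed as "activations" below sums to 1260 and the one
# printed as "repressions" sums to 687. The table is preserved as printed;
# sign-class totals should be compared label-agnostically (min/max).
tf_id	alias	connections	activations	repressions
AT1G74950	TIFY10B	258	238	20
AT4G11660	HSFB2B	182	21	161
AT1G28050	AT1G28050	149	120	29
AT5G49330	MYB111	131	114	17
AT5G16600	MYB43	123	79	44
AT5G47640	NF-YB2	120	97	23
AT5G44260	AT5G44260	99	36	63
AT5G57660	COL5	81	23	58
AT4G18880	HSF A4A	79	52	27
AT1G46264	HSFB4	67	61	6
AT3G24500	MBF1C	58	49	9
AT2G34720	NF-YA4	53	33	20
AT1G79700	AT1G79700	52	14	38
AT5G11590	TINY2	51	41	10
AT4G25480	DREB1A	49	37	12
AT5G44190	GLK2	47	37	10
AT5G02810	PRR7	36	28	8
AT5G24470	APRR5	35	23	12
AT4G34680	GATA-3	34	27	7
AT5G25190	AT5G25190	25	11	14
AT4G28190	ULT1	24	11	13
AT4G36990	HSF4	21	6	15
AT4G37260	MYB73	21	11	10
AT3G15540	IAA19	20	15	5
AT1G70700	TIFY7	17	10	7
AT2G40350	AT2G40350	15	7	8
AT3G51910	HSFA7A	15	10	5
AT3G62090	PIL2	14	6	8
AT4G29080	PAP2	14	13	1
AT3G50750	AT3G50750	12	2	10
AT3G59060	PIL6	11	7	4
AT3G47500	CDF3	10	3	7
AT1G71030	MYBL2	9	8	1
AT2G26150	HSFA2	9	6	3
AT4G37790	HAT22	6	4	2
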