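# Curated heat-responsive transcription factors. The study drew on a curated
# list of 59 previously known heat-regulated TFs (GO "response to heat" or
# "heat shock factor"); only the 35 members that were also differentially
# regulated in the arrays are printed, and those 35 are transcribed here.
# The remaining 24 loci of the curated list are not published.
tf_id	alias
AT1G28050	AT1G28050
AT1G46264	HSFB4
AT1G70700	TIFY7
AT1G71030	MYBL2
AT1G74950	TIFY10B
AT1G79700	AT1G79700
AT2G26150	HSFA2
AT2G34720	NF-YA4
AT2G40350	AT2G40350
AT3G15540	IAA19
AT3G24500	MBF1C
AT3G47500	CDF3
AT3G50750	AT3G50750
AT3G51910	HSFA7A
AT3G59060	PIL6
AT3G62090	PIL2
AT4G11660	HSFB2B
AT4G18880	HSF A4A
AT4G25480	DREB1A
AT4G28190	ULT1
AT4G29080	PAP2
AT4G34680	GATA-3
AT4G36990	HSF4
AT4G37260	MYB73
AT4G37790	HAT22
AT5G02810	PRR7
AT5G11590	TINY2
AT5G16600	MYB43
AT5G24470	APRR5
AT5G25190	AT5G25190
AT5G44190	GLK2
AT5G44260	AT5G44260
AT5G47640	NF-YB2
AT5G49330	MYB111
AT5G57660	COL5
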