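# Ecotype-specific transcriptional activity calls for the 35 heat-responsive
# TFs, transcribed from the printed table: the ecotypes in which each TF's
# inferred activity was called responsive. Format-only fixture — the calls
# cannot be recomputed without the original array data and threshold.
tf_id	alias	ecotypes
AT1G74950	TIFY10B	Kond;An-1;Sha
AT4G11660	HSFB2B	Cvi
AT1G28050	AT1G28050	Kyo-2;An-1;Col;Sha
AT5G49330	MYB111	Cvi
AT5G16600	MYB43	Kas-1;Kond;An-1;Sha
AT5G47640	NF-YB2	Cvi;Eri
AT5G44260	AT5G44260	An-1
AT5G57660	COL5	Cvi
AT4G18880	HSF A4A	Kas-1;An-1
AT1G46264	HSFB4	Kas-1;Sha
AT3G24500	MBF1C	Kas-1;Eri
AT2G34720	NF-YA4	An-1;Sha
AT1G79700	AT1G79700	Kond;An-1
AT5G11590	TINY2	Eri;Kond;Col
AT4G25480	DREB1A	Cvi
AT5G44190	GLK2	Cvi;Kas-1
AT5G02810	PRR7	Kond
AT5G24470	APRR5	Col
AT4G34680	GATA-3	Cvi;Kas-1
AT5G25190	AT5G25190	Eri;Kond;C24;An-1
AT4G28190	ULT1	Kond;Sha
AT4G36990	HSF4	Cvi;Kas-1;Sha
AT4G37260	MYB73	Kas-1;Kond;Col
AT3G15540	IAA19	Eri
AT1G70700	TIFY7	Kas-1;An-1
AT2G40350	AT2G40350	Kyo-2;Eri
AT3G51910	HSFA7A	Eri;Kond
AT3G62090	PIL2	Col
AT4G29080	PAP2	Kond
AT3G50750	AT3G50750	Col
AT3G59060	PIL6	Kas-1
AT3G47500	CDF3	Kas-1;C24;Sha
AT1G71030	MYBL2	Eri
AT2G26150	ATHSFA2	Ler;Kond;C24;Sha
AT4G37790	HAT22	Ler;Kas-1
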