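# Summary of the ten A. thaliana ecotypes and their differential-expression
# pattern under heat stress (38 C vs control), transcribed from the printed
# summary table. Counts are numbers of transcripts significant at p <= 0.01.
# "unique" columns count transcripts significant in that ecotype only.
ecotype	origin	latitude_north	total	total_up	total_down	unique_total	unique_up	unique_down
Cvi	Cape Verdia Islands	16	776	405	371	649	348	301
Kas-1	Kashmir, India	34	797	334	463	569	219	350
Kyo-2	Kyoto city, western part of Hoshu Island, Japan	35.5	476	247	229	324	159	165
Sha	Shakdara, Pamiro-Alay, Tadjikistan	39	355	178	177	206	92	114
Col-0	Columbia, United States	38.5	143	80	63	105	56	49
Kond	Kondara, Tadjikistan	38.8	281	115	166	183	72	111
C24	Coimbra, Portugal	40	215	116	99	115	60	55
Ler	Landsberg, Poland	48	276	138	138	224	113	111
An-1	Antwerpern, Belgium	51.5	670	226	444	450	137	313
Eri	Erigsboda, Sweden	56	442	301	141	290	193	97
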