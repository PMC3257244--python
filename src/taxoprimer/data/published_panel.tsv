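assay_name	target	level	forward_name	forward_seq	reverse_name	reverse_seq	expected_sizes	conc_um	annealing_c	mgcl2_mm	multiplex
Fagopyrum_esculentum_380	Fagopyrum esculentum	species	Fag-sp-S519	gaaaacgaaaggaaaggttcat	Fag-sp-A523	caggattacccgttttttga	380	0.2	56	4	FLPS
Lolium_perenne_254	Lolium perenne	species	Lol-per-S528	gcatttttctatatagaatggat	Lol-per-A535	tgactctatgttctccttagtt	254	0.4	56	4	FLPS
Phaseolus_coccineus_235	Phaseolus coccineus	species	Pha-sp-S525	atcctttcacaaaaattccag	Pha-sp-A531	tggatcagttcttcaagggt	235	0.2	56	4	FLPS
Sinapis_alba_203	Sinapis alba	species	Sin-alb-S534	attcactaaactactagatcgt	Sin-alb-A542	catgaaatcaaaattcgaaagtc	203	0.4	56	4	FLPS
Lupinus_angustifolius_244	Lupinus angustifolius	species	Lup-sp-S522	gaatccattcaacagttctg	Lup-sp-A527	gaacttttctttgtttttgcg	244	0.2	53	4	LF
Fagopyrum_esculentum_206	Fagopyrum esculentum	species	Fag-sp-S519	gaaaacgaaaggaaaggttcat	Fag-sp-A524	tattaccctttcataccgcat	206	0.2	53	4	LF
Taraxacum_officinale_194	Taraxacum officinale	species	Tar-sp-S546	cggttcaaaactcctttatg	Tar-sp-A554	ttcctcatgtctcatcctt	194	0.2	58	4	TAT
Achillea_millefolium_222	Achillea millefolium	species	Ach-sp-S547	gcggttcaaaattccttatac	Ach-sp-A556	agggtattacaaagactcg	222	0.2	58	4	TAT
Trifolium_repens_172	Trifolium repens	species	Tri-sp-S550	cagtaggaaaggaatcgttct	Tri-sp-A558	aatctttcatttgtgatagaaaag	172	0.2	58	4	TAT
Trifolium_pratense_151	Trifolium pratense	species	Tri-sp-S550	cagtaggaaaggaatcgttct	Tri-sp-A558	aatctttcatttgtgatagaaaag	151	0.2	58	4	TAT
Triticum_aestivum_306	Triticum aestivum	species	Tri-aes-S536	gctattaactagttctaaatttgaagtta	Tri-aes-A545	cctcccgtcttacttttttat	306	0.5	54	4	TZ
Zea_mays_181	Zea mays	species	Zea-may-S510	atttgatcattatatacatttttgagat	Zea-may-A539	tccttccttttttagagtattcc	181	0.2	54	4	TZ
Plantago_116	Plantago	genus	Pla-sp-S557	atctattttctagctatcctacc	Pla-sp-A565	cgcatgtgataagagaaagtc	116	0.5	61.5	4	singleplex
Apiaceae_198	Apiaceae	family	Api-gen-S561	aatgaccgtctttgaccaaa	Api-gen-A569	attctcattcccgatatcgc	198/199	0.5	62	3	singleplex
Poaceae_187_293	Poaceae	family	Poa-gen-S541	gctttctcattctactctttc	Poa-gen-A551	cttttcttgtgcatcatcctag	187-293	0.2	56	3	singleplex
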