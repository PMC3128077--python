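organism	sub2_accession	sub2_tm	sub2_mm	iia_accession	iia_tm	iia_mm
Aquifex aeolicus	NP_214505	1	16700	Not annotated	1	5108
Thermus thermophilus	YP_144400	1	18563	YP_144399	1	3766
Exiguobacterium siribium	YP_001813095	1	13809	YP_001813094	1	3825
Thermomicrobium roseum	YP_002521803	1	16597	YP_002521802	1	4919
Bacillus halodurans	NP_241606	1	17447	NP_241607	1	4638
Rhodothermus marinus	YP_003290840.1	1	17263	YP_003290841.1	1	5371
Roseiflexus castenholzii DSM 13941	YP_001431685	1	18069	YP_001431684	1	6065
Methylococcus capsulatus str. Bath	YP_114812	1	19354	YP_114814	1	5354
Burkholderia multivorans ATCC17616	YP_001585718	1	21154	YP_001585719	1	7148
Oceanobacillus iheyensis HTE831	NP_692666	1	18390	Not annotated	1	5071
Chloroflexus aurantiacus J-10-fl	YP_001636023	1	13236	YP_001636022	1	5824
Bradhyrizobium japonicum USDA 110	NP_771121	1	19992	Not annotated	1	5972
Thermocrinis albus DSM 14484	YP_003474329	1	16155	YP_003474328	1	6366
Geobacillus spC56T3	YP_003671527	1	16881	YP_003671526	1	5387
Hydrogenivirga sp.128-5-R1-1	ZP_02176551	1	16560	ZP_02176552	1	4355
Hydrogenobacter thermophilus TK-6	YP_003433136	1	16543	YP_003433135	1	4255
Sphaerobacter thermophilus DSM 20745	YP_003320090	1	13114	YP_003320089	1	7847
Meiothermus silvanus DSM 9946	YP_003685401	1	17733	YP_003685402	1	3944
Salinibacter ruber DSM 13855	YP_444459	1	18901	Not annotated	1	7196
Deinococcus geothermalis DSM 11300	YP_603489	1	19744	Not annotated	1	5529
Magnetospirillum magneticum AMB-1	YP_421584	1	20462	YP_421583	1	5828
Rhizobium etli CFN42	YP_468521	1	19731	Not annotated	1	5911
Natrialba magadii ATCC 43099	YP_003481905	1	28596	YP_003481904	1	6080
Haloferax volcanii DS2	YP_003535001	1	19378	YP_003535000	1	7986
Natronomonas pharaonis	CAA71530	1	18628	CAA71529	1	6081
Haloterrigena turkmenica DSM 5511	YP_003402035	1	27982	YP_003402036	1	8496
Halorubrum lacusprofundi ATCC 49239	YP_002567057	1	15188	YP_002567056	1	7223
Nitrobacter hamburgensis X14	YP_577951	2	19699	Absent	-	-
Silicibacter pomeroyi DSS-3	YP_165014	2	18559	Absent	-	-
Geobacillus kaustophilus HTA426	YP_147523.1	2	20134	Absent	-	-
Sulfurimonas denitrificans DSM 1251	YP_392619	2	22228	Absent	-	-
Nitrosomonas europaea ATCC 19718	NP_840763	2	19364	Absent	-	-
Nocardioides sp. JS614	YP_922822	2	21603	Absent	-	-
Nitrosococcus oceani ATCC 19707	YP_344943	2	19857	Absent	-	-
Aromatoleum aromaticum EbN1	YP_159093	2	19656	Absent	-	-
Sulfurovum sp. NBC37-1	YP_001357603	2	23477	Absent	-	-
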