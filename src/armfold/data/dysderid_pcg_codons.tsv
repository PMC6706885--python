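gene	species	length	start_codon	stop_codon
nad2	P_teruelis	927	ATA	TAA
nad2	P_riberai	927	ATT	TAG
nad2	H_apennicola	926	ATT	TA
nad2	P_romandiolae	927	ATT	TAA
nad2	P_limbarae	926	ATT	TA
nad2	P_ignavus	927	ATT	TAA
cox1	P_teruelis	1533	TTA	TAA
cox1	P_riberai	1533	ATA	TAG
cox1	H_apennicola	1533	TTA	TAG
cox1	P_romandiolae	1533	GTA	TAG
cox1	P_limbarae	1533	GTA	TAA
cox1	P_ignavus	1533	GTA	TAG
cox2	P_teruelis	658	ATT	T
cox2	P_riberai	660	GTG	TAG
cox2	H_apennicola	658	GTG	T
cox2	P_romandiolae	660	GTG	TAG
cox2	P_limbarae	660	ATA	TAG
cox2	P_ignavus	657	GTG	TAA
atp8	P_teruelis	150	ATA	TAA
atp8	P_riberai	150	ATT	TAA
atp8	H_apennicola	150	ATT	TAA
atp8	P_romandiolae	150	ATT	TAA
atp8	P_limbarae	150	ATT	TAA
atp8	P_ignavus	150	ATT	TAA
atp6	P_teruelis	666	ATG	TAG
atp6	P_riberai	666	ATG	TAG
atp6	H_apennicola	666	TTG	TAG
atp6	P_romandiolae	666	ATG	TAG
atp6	P_limbarae	666	ATG	TAA
atp6	P_ignavus	666	ATG	TAA
cox3	P_teruelis	789	ATA	TAA
cox3	P_riberai	789	ACA	TAA
cox3	H_apennicola	788	AAA	TA
cox3	P_romandiolae	789	GTA	TAG
cox3	P_limbarae	789	TTA	TAA
cox3	P_ignavus	789	ATA	TAG
nad3	P_teruelis	336	ATA	TAA
nad3	P_riberai	336	ATA	TAA
nad3	H_apennicola	336	ATT	TAA
nad3	P_romandiolae	336	ATT	TAA
nad3	P_limbarae	336	CTG	TAA
nad3	P_ignavus	336	ATT	TAA
nad5	P_teruelis	1649	ATT	TA
nad5	P_riberai	1650	ATC	TAA
nad5	H_apennicola	1644	AAT	TAA
nad5	P_romandiolae	1649	ATT	TA
nad5	P_limbarae	1637	ATT	TA
nad5	P_ignavus	1650	ATC	TAA
nad4	P_teruelis	1277	ATA	TA
nad4	P_riberai	1278	ATA	TAA
nad4	H_apennicola	1277	ATA	TA
nad4	P_romandiolae	1276	ATA	T
nad4	P_limbarae	1277	ATA	TA
nad4	P_ignavus	1276	ATA	T
nad4L	P_teruelis	263	ATA	TA
nad4L	P_riberai	263	ATT	TA
nad4L	H_apennicola	263	ATT	TA
nad4L	P_romandiolae	263	ATC	TA
nad4L	P_limbarae	263	ATA	TA
nad4L	P_ignavus	263	ATT	TA
nad6	P_teruelis	433	ATA	T
nad6	P_riberai	434	ACA	TA
nad6	H_apennicola	436	TTG	T
nad6	P_romandiolae	434	TTA	TA
nad6	P_limbarae	434	TTG	TA
nad6	P_ignavus	434	TTA	TA
cob	P_teruelis	1134	GTG	TAG
cob	P_riberai	1128	ATG	TAG
cob	H_apennicola	1137	GTG	TAA
cob	P_romandiolae	1128	ATG	TAG
cob	P_limbarae	1128	ATG	TAG
cob	P_ignavus	1128	ATG	TAG
nad1	P_teruelis	903	ATA	TAA
nad1	P_riberai	903	ATT	TAA
nad1	H_apennicola	909	ACT	TAG
nad1	P_romandiolae	903	ATA	TAA
nad1	P_limbarae	906	ATA	TAA
nad1	P_ignavus	903	ATA	TAA
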