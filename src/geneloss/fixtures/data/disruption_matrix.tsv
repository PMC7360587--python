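species	gene_id	kind	exon_index	cds_nt_pos	codon_index	indel_len	allele	stop_context	splice_site	observed_site	cluster_id	validation	n_supporting_projects
Orcinus_orca	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Orcinus_orca	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Tursiops_truncatus	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Tursiops_truncatus	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Delphinapterus_leucas	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Delphinapterus_leucas	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Neophocaena_asiaeorientalis	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Neophocaena_asiaeorientalis	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Lipotes_vexillifer	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Lipotes_vexillifer	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Physeter_catodon	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Physeter_catodon	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Balaenoptera_acutorostrata	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Balaenoptera_acutorostrata	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Balaena_mysticetus	GBA3	premature_stop	3	598	200	0	TAG	DSLFX			CET-DSLFX	validated_fixed	2
Balaena_mysticetus	GBA3	premature_stop	3	748	250	0	TAA	YTTRX			CET-YTTRX	validated_fixed	2
Physeter_catodon	GBA3	deletion	4	920	307	2	GT					validated_fixed	2
Balaena_mysticetus	GBA3	premature_stop	5	1210	404	0	TGA	KWTNX				validated_fixed	2
Leptonychotes_weddellii	GBA3	deletion	3	700	234	13	ACGTACGTACGTA				PHO-del13	validated_fixed	2
Mirounga_angustirostris	GBA3	deletion	3	700	234	13	ACGTACGTACGTA				PHO-del13	validated_fixed	2
Phoca_vitulina	GBA3	deletion	3	700	234	13	ACGTACGTACGTA				PHO-del13	validated_fixed	2
Callorhinus_ursinus	GBA3	premature_stop	3	538	180	0	TGA	DSLFX			OTA-stop	validated_fixed	2
Zalophus_californianus	GBA3	premature_stop	3	538	180	0	TGA	DSLFX			OTA-stop	validated_fixed	2
Eumetopias_jubatus	GBA3	premature_stop	3	538	180	0	TGA	DSLFX			OTA-stop	validated_fixed	2
Odobenus_rosmarus_divergens	GBA3	deletion	3	650	217	1	G					validated_fixed	2
Odobenus_rosmarus_divergens	GBA3	insertion	4	905	302	2	CA					validated_fixed	2
Odobenus_rosmarus_divergens	GBA3	deletion	5	1200	400	4	TTCA					validated_fixed	2
Vulpes_vulpes	GBA3	deletion	3	600	200	1	C					validated_polymorphic	2
Lycaon_pictus	GBA3	premature_stop	3	568	190	0	TAA	SMRQX				validated_polymorphic	2
Heterocephalus_glaber	GBA3	premature_stop	3	463	155	0	TAA	GELPX				validated_fixed	2
Heterocephalus_glaber	GBA3	premature_stop	3	628	210	0	TGA	AKVMX				validated_fixed	2
Fukomys_damarensis	GBA3	premature_stop	3	472	158	0	TAG	PNVRX				validated_fixed	2
Fukomys_damarensis	GBA3	premature_stop	3	643	215	0	TAA	LDGTX				validated_fixed	2
Mus_musculus	GBA3	premature_stop	3	454	152	0	TGA	EHFRX				validated_fixed	2
Mus_musculus	GBA3	premature_stop	3	658	220	0	TAA	WQRVX				validated_fixed	2
Mus_musculus	GBA3	insertion	2	300	100	4	ATCG					validated_fixed	2
Pteropus_vampyrus	GBA3	deletion	3	710	237	10	GATTACACAT					validated_fixed	2
Pteropus_vampyrus	GBA3	premature_stop	4	898	300	0	TAA	TRLSX				validated_polymorphic	2
Pteropus_vampyrus	GBA3	premature_stop	5	1318	440	0	TAG	NIEVX			PTE-ex5stop	validated_fixed	2
Pteropus_alecto	GBA3	premature_stop	3	508	170	0	TAA	QGFDX				validated_polymorphic	2
Pteropus_alecto	GBA3	premature_stop	5	1318	440	0	TAG	NIEVX			PTE-ex5stop	validated_fixed	2
Desmodus_rotundus	GBA3	premature_stop	3	613	205	0	TAA	FPLKX				unvalidated	1
Desmodus_rotundus	GBA3	deletion	4	950	317	2	AG					unvalidated	1
Loxodonta_africana	GBA3	premature_stop	3	493	165	0	TAA	HGWEX				unvalidated	1
Loxodonta_africana	GBA3	premature_stop	3	523	175	0	TGA	IVSPX				unvalidated	1
Loxodonta_africana	GBA3	premature_stop	3	553	185	0	TAA	CNQLX				unvalidated	1
Loxodonta_africana	GBA3	splice_loss	4	865	289	0	AA		acceptor	AA		unvalidated	1
Loxodonta_africana	GBA3	premature_stop	4	958	320	0	TAA	MKGDX				unvalidated	1
Trichechus_manatus_latirostris	GBA3	premature_stop	3	502	168	0	TAA	VYENX				validated_fixed	2
Trichechus_manatus_latirostris	GBA3	premature_stop	3	718	240	0	TGA	SSIGX				validated_fixed	2
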