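((Loxodonta_africana:0.08,Trichechus_manatus_latirostris:0.09):0.04,((((Homo_sapiens:0.02,Pan_troglodytes:0.02):0.03,Macaca_mulatta:0.05):0.04,((Mus_musculus:0.08,Rattus_norvegicus:0.08):0.06,((Heterocephalus_glaber:0.06,Fukomys_damarensis:0.06):0.03,Cavia_porcellus:0.08):0.04):0.05):0.03,((((Pteropus_vampyrus:0.02,Pteropus_alecto:0.02):0.04,Rousettus_aegyptiacus:0.05):0.02,(Desmodus_rotundus:0.07,Myotis_lucifugus:0.07):0.03):0.05,((((Felis_catus:0.04,Panthera_tigris:0.04):0.02,Suricata_suricatta:0.06):0.04,((Vulpes_vulpes:0.04,(Lycaon_pictus:0.02,Canis_lupus_familiaris:0.02):0.02):0.04,((Odobenus_rosmarus_divergens:0.03,(Callorhinus_ursinus:0.02,(Zalophus_californianus:0.01,Eumetopias_jubatus:0.01):0.01):0.02):0.02,(Leptonychotes_weddellii:0.02,(Mirounga_angustirostris:0.02,Phoca_vitulina:0.02):0.01):0.02):0.03):0.03):0.02,((Bos_taurus:0.04,(Ovis_aries:0.02,Capra_hircus:0.02):0.02):0.04,((Balaenoptera_acutorostrata:0.02,Balaena_mysticetus:0.02):0.02,(Physeter_catodon:0.03,(Lipotes_vexillifer:0.02,(Neophocaena_asiaeorientalis:0.02,(Delphinapterus_leucas:0.01,(Orcinus_orca:0.01,Tursiops_truncatus:0.01):0.005):0.005):0.005):0.005):0.01):0.03):0.03):0.02):0.02):0.02);
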