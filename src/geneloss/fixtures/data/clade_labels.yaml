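# Clade and branch labels of the selection analysis: seven mammalian clades
# and the two ancestral (stem) branches of Pinnipedia and Cetacea.
clades:
  A1:  # Pinnipedia
    - Odobenus_rosmarus_divergens
    - Callorhinus_ursinus
    - Zalophus_californianus
    - Eumetopias_jubatus
    - Leptonychotes_weddellii
    - Mirounga_angustirostris
    - Phoca_vitulina
  A2:  # Canidae
    - Vulpes_vulpes
    - Lycaon_pictus
    - Canis_lupus_familiaris
  A3:  # Feliformia
    - Felis_catus
    - Panthera_tigris
    - Suricata_suricatta
  B1:  # Cetacea
    - Balaenoptera_acutorostrata
    - Balaena_mysticetus
    - Physeter_catodon
    - Lipotes_vexillifer
    - Neophocaena_asiaeorientalis
    - Delphinapterus_leucas
    - Orcinus_orca
    - Tursiops_truncatus
  B2:  # Ruminantia
    - Bos_taurus
    - Ovis_aries
    - Capra_hircus
  C1:  # Chiroptera
    - Pteropus_vampyrus
    - Pteropus_alecto
    - Rousettus_aegyptiacus
    - Desmodus_rotundus
    - Myotis_lucifugus
  D1:  # Rodentia
    - Mus_musculus
    - Rattus_norvegicus
    - Heterocephalus_glaber
    - Fukomys_damarensis
    - Cavia_porcellus
branches:
  BranchA1:  # Pinnipedia stem
    - Odobenus_rosmarus_divergens
    - Callorhinus_ursinus
    - Zalophus_californianus
    - Eumetopias_jubatus
    - Leptonychotes_weddellii
    - Mirounga_angustirostris
    - Phoca_vitulina
  BranchB1:  # Cetacea stem
    - Balaenoptera_acutorostrata
    - Balaena_mysticetus
    - Physeter_catodon
    - Lipotes_vexillifer
    - Neophocaena_asiaeorientalis
    - Delphinapterus_leucas
    - Orcinus_orca
    - Tursiops_truncatus
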