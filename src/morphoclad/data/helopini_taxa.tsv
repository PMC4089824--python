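taxon	tribe	subtribe	region	is_outgroup	is_root
Uloma_mexicana	Ulomini		Mexico, Central America	1	1
Helops_punctipennis	Helopini	Helopina	U.S.A.	0	0
Entomogonus_peyronis	Helopini	Helopina	Asia	0	0
Raiboscelis_corvinus	Helopini	Helopina	Asia, Europe	0	0
Probaticus_tentyrioides	Helopini	Helopina	Asia, Europe	0	0
Helops_rossii	Helopini	Helopina	Europe	0	0
Helops_insignis	Helopini	Helopina	North of Africa	0	0
Helops_cisteloides	Helopini	Helopina	U.S.A.	0	0
Nautes_enoplopoides	Helopini	unassigned	Guatemala	0	0
Helops_perforatus	Helopini	Helopina	Mexico, U.S.A.	0	0
Nautes_striatipennis	Helopini	unassigned	Mexico	0	0
Helops_farctus	Helopini	Helopina	U.S.A.	0	0
Nautes_splendens	Helopini	unassigned	Panama	0	0
Tarpela_browni	Helopini	Helopina	Nicaragua	0	0
Tarpela_torrida	Helopini	Helopina	Mexico	0	0
Nautes_magnificus	Helopini	unassigned	Guatemala	0	0
Tarpela_depressa	Helopini	Helopina	Mexico	0	0
Nautes_varians	Helopini	unassigned	Mexico	0	0
Tarpela_contigua	Helopini	Helopina	Mexico	0	0
Nautes_belti	Helopini	unassigned	Central America	0	0
Nautes_fervidus	Helopini	unassigned	Mexico, Central America	0	0
Tarpela_aerifera	Helopini	Helopina	Mexico, Central America	0	0
Tarpela_reticulata	Helopini	Helopina	Honduras	0	0
Helops_rufipes	Helopini	Helopina	Mexico, U.S.A.	0	0
Helops_inanis	Helopini	Helopina	Mexico	0	0
Tarpela_costata	Helopini	Helopina	Mexico, Nicaragua	0	0
Nalassus_plebejus	Helopini	Cylindrinotina	Europe, Asia	0	0
Helops_aereus	Helopini	Helopina	U.S.A.	0	0
Odocnemis_californicus	Helopini	Cylindrinotina	Mexico, U.S.A.	0	0
Stenomax_aeneus	Helopini	Cylindrinotina	Europe	0	0
Tarpela_cordicollis	Helopini	Helopina	Japan	0	0
Hypogena_biimpressa	Ulomini		Mexico, Central America, South America	1	0
Tenebrio_molitor	Tenebrionini		global	1	0
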