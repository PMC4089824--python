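xread
67 33
Uloma_mexicana           1011000110111101210100001011011110?1003000-011011202--001-001211122
Helops_punctipennis      110130110201110121011011111111011111002000-020101000000101000101111
Entomogonus_peyronis     110000?100011201010111110-1111121110101000-02010100???100001-0110?0
Raiboscelis_corvinus     0100301100011131010111110-111002?110101000-01010100100100001-011000
Probaticus_tentyrioides  110020210101113101001--10-1100011110111000-01010100100110101-011000
Helops_rossii            1100000100011101210110100-1111111110101000-01010100100100001-011000
Helops_insignis          1100300100011101210110110-1111111110101000-01010100100100001-011000
Helops_cisteloides       1100201101011101010111100-1100020111100000-02010100101000101-011000
Nautes_enoplopoides      0101?0112-0121012010?0110-101002111011001101--10200010110111-011111
Helops_perforatus        010020110101110111011110011111121110110011100010210000110101-101111
Nautes_striatipennis     0101101101010101200110101100000211101100110010102000011101101011111
Helops_farctus           0101211101010101200010000-11000011101110110010102000011101100011111
Nautes_splendens         01012021221001012010011011000000111???10110010102000011101101011111
Tarpela_browni           1101?010000100102001?110111100101110110011001010200000110111-011101
Tarpela_torrida          01012021001101012011?120111101101110111011012010200001110111-011111
Nautes_magnificus        0101201012101111201010000100000111101110110010102000011101101011111
Tarpela_depressa         0100?011120111012011000011110110111011101110001020-000110101-101111
Nautes_varians           000100110101010120001000111100-011101100110010102000011111101011101
Tarpela_contigua         0001202101011101010111111111111211101?0011100010200000110101-101111
Nautes_belti             0101202112011101200110101100010011001110110021102000011101101011111
Nautes_fervidus          010120?1221001012010001011000000111111101101--102000011101101011111
Tarpela_aerifera         01002021120110002001112011110100111011101101-0102001011101101011101
Tarpela_reticulata       11012010000010102001?12011100110111011001100-010200001010111-011111
Helops_rufipes           1100011101012231010101210-1111110110001000-020101000001101101111110
Helops_inanis            0100200102011101010111110-1111111010111011001010200001111101-111111
Tarpela_costata          010000100001101120000120110011121110110011001010200001110111-011101
Nalassus_plebejus        110000111201010120011000101101121000111101-01000110100111-01-110100
Helops_aereus            1100001102010101210111000-1101101000111101-02000111100111-01-110100
Odocnemis_californicus   110020110201110101011010101101101000111001-02010111100111-01-110100
Stenomax_aeneus          110020210101110101020110011110011000111001-00110120100001-010110000
Tarpela_cordicollis      110020201201110101011010101101121100111001-02000111110111-011110100
Hypogena_biimpressa      101021211020010121010010101111121111102001-1--11-21100101-01-011022
Tenebrio_molitor         001101011211120121111001111011120010013000-1--10000010011-01-011100
;
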