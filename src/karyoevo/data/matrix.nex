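#NEXUS
BEGIN TAXA;
    DIMENSIONS NTAX=55;
    TAXLABELS
        Hyloscirtus_alytolylax
        Hyloscirtus_palmeri
        Hyloscirtus_larinopygion
        Boana_cf._alfaroi
        Boana_leucocheila
        Boana_multifasciata
        Boana_almendarizae
        Boana_calcarata
        Boana_cf._lanciformis
        Boana_heilprini
        Boana_raniceps
        Boana_faber
        Boana_pellucens
        Boana_cinerascens
        Boana_punctata
        Boana_boans
        Boana_cf._semilineata
        Boana_wavrini
        Boana_albonigra
        Boana_bischoffi
        Boana_caingua
        Boana_cipoensis
        Boana_cordobae
        Boana_curupi
        Boana_marianitae
        Boana_pulchella
        Boana_riojana
        Boana_stellae
        Myersiohyla
        Hyloscirtus_armatus
        Bokermannohyla_alvarengai
        Bokermannohyla_ibitiguara
        Aplastodiscus_perviridis
        Aplastodiscus_cochranae
        Aplastodiscus_albosignatus
        Aplastodiscus_callipygius
        Aplastodiscus_leucopygius
        Aplastodiscus_albofrenatus
        Aplastodiscus_arildae
        Aplastodiscus_ehrhardti
        Aplastodiscus_eugenioi
        Boana_albopunctata
        Boana_fasciata
        Boana_prasina
        Boana_joaquini
        Boana_semiguttata
        Boana_pombali
        Boana_geographica
        Boana_semilineata
        Bokermannohyla_spp.
        Dendropsophini
        Hylini
        Lophyohylini
        Pelodryadinae
        Phyllomedusinae
    ;
END;
BEGIN CHARACTERS;
    DIMENSIONS NCHAR=2;
    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789A" MISSING=?;
    CHARSTATELABELS 1 x, 2 nor_pair;
    [STATEKEY x: 9=0 10=1 11=2 12=3 13=4; nor_pair: 1=0 2=1 6=2 7=3 8=4 9=5 11=6 12=7 4a=8 4b=9 4c=A]
    MATRIX
        Hyloscirtus_alytolylax      19
        Hyloscirtus_palmeri         3A
        Hyloscirtus_larinopygion    30
        Boana_cf._alfaroi           24
        Boana_leucocheila           24
        Boana_multifasciata         24
        Boana_almendarizae          37
        Boana_calcarata             3?
        Boana_cf._lanciformis       36
        Boana_heilprini             3?
        Boana_raniceps              36
        Boana_faber                 36
        Boana_pellucens             36
        Boana_cinerascens           36
        Boana_punctata              36
        Boana_boans                 33
        Boana_cf._semilineata       33
        Boana_wavrini               36
        Boana_albonigra             36
        Boana_bischoffi             36
        Boana_caingua               37
        Boana_cipoensis             30
        Boana_cordobae              36
        Boana_curupi                30
        Boana_marianitae            36
        Boana_pulchella             37
        Boana_riojana               36
        Boana_stellae               30
        Myersiohyla                 ??
        Hyloscirtus_armatus         3?
        Bokermannohyla_alvarengai   38
        Bokermannohyla_ibitiguara   30
        Aplastodiscus_perviridis    36
        Aplastodiscus_cochranae     36
        Aplastodiscus_albosignatus  16
        Aplastodiscus_callipygius   ?6
        Aplastodiscus_leucopygius   06
        Aplastodiscus_albofrenatus  22
        Aplastodiscus_arildae       26
        Aplastodiscus_ehrhardti     22
        Aplastodiscus_eugenioi      22
        Boana_albopunctata          24
        Boana_fasciata              3?
        Boana_prasina               ?{57}
        Boana_joaquini              ?0
        Boana_semiguttata           ?0
        Boana_pombali               ?3
        Boana_geographica           ?0
        Boana_semilineata           ?3
        Bokermannohyla_spp.         36
        Dendropsophini              36
        Hylini                      36
        Lophyohylini                36
        Pelodryadinae               4?
        Phyllomedusinae             4?
    ;
END;
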