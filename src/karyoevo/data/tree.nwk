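((Phyllomedusinae,Pelodryadinae),((Dendropsophini,Hylini,Lophyohylini),(Myersiohyla,(((Hyloscirtus_alytolylax,Hyloscirtus_palmeri)H._bogotensis_group,(Hyloscirtus_armatus,Hyloscirtus_larinopygion))Hyloscirtus,((Bokermannohyla_alvarengai,Bokermannohyla_ibitiguara,Bokermannohyla_spp.)Bokermannohyla,(((Aplastodiscus_perviridis,Aplastodiscus_cochranae)A._perviridis_group,(Aplastodiscus_albosignatus,Aplastodiscus_callipygius,Aplastodiscus_leucopygius)A._albosignatus_group,(Aplastodiscus_albofrenatus,(Aplastodiscus_arildae,(Aplastodiscus_ehrhardti,Aplastodiscus_eugenioi)))A._albofrenatus_group)Aplastodiscus,(((Boana_albopunctata,Boana_cf._alfaroi,Boana_leucocheila,Boana_multifasciata)B._albopunctata_2n22_clade,Boana_almendarizae,Boana_calcarata,Boana_cf._lanciformis,Boana_fasciata,Boana_heilprini,Boana_raniceps)B._albopunctata_group,Boana_faber,Boana_pellucens,(Boana_cinerascens,Boana_punctata)B._punctata_group,(Boana_boans,Boana_cf._semilineata,Boana_geographica,Boana_pombali,Boana_semilineata,Boana_wavrini)B._semilineata_group,((Boana_cipoensis,(Boana_curupi,Boana_joaquini,Boana_semiguttata,Boana_stellae)B._semiguttata_clade)B._polytaenia_semiguttata_clade,(Boana_caingua,Boana_prasina,Boana_pulchella)B._pulchella_12_clade,Boana_albonigra,Boana_bischoffi,Boana_cordobae,Boana_marianitae,Boana_riojana)B._pulchella_group)Boana))))Cophomantini)Hylinae)Hylidae;
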