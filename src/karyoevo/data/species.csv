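species,genus,species_group,studied_here,specimen_level,n_specimens,techniques,x,nor_pairs_raw,nor_position,c_band_known,caution,source,provenance
"Hyloscirtus alytolylax",Hyloscirtus,"H. bogotensis",1,0,2F3M,"Ag-NORs;C-bands;DAPI/CMA3",10,4,terminal,1,0,this_study,results:hyloscirtus
"Hyloscirtus palmeri",Hyloscirtus,"H. bogotensis",1,0,1F,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,4,terminal,1,0,this_study,results:hyloscirtus
"Hyloscirtus larinopygion",Hyloscirtus,"H. larinopygion",1,0,2M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,1,terminal,1,0,this_study,results:hyloscirtus
"Boana cf. alfaroi",Boana,"B. albopunctata",1,0,1M1U,"rDNA-FISH",11,8,terminal,0,0,this_study,results:albopunctata-group
"Boana leucocheila",Boana,"B. albopunctata",1,0,3M,"Ag-NORs;DAPI/CMA3;rDNA-FISH",11,8,terminal,0,0,this_study,results:albopunctata-group
"Boana multifasciata",Boana,"B. albopunctata",1,0,3M1U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",11,8,terminal,1,0,this_study,results:albopunctata-group
"Boana almendarizae",Boana,"B. albopunctata",1,0,2M,"Ag-NORs;C-bands;DAPI/CMA3",12,12,terminal,1,0,this_study,results:albopunctata-group
"Boana calcarata",Boana,"B. albopunctata",1,0,1M,"C-bands",12,,,1,0,this_study,results:albopunctata-group
"Boana cf. lanciformis",Boana,"B. albopunctata",1,0,1M,"Ag-NORs",12,11,terminal,0,0,this_study,results:albopunctata-group
"Boana heilprini",Boana,"B. albopunctata",1,0,1F1M,"DAPI/CMA3",12,,,0,0,this_study,results:albopunctata-group
"Boana raniceps",Boana,"B. albopunctata",1,0,1F14M1J2U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,terminal,1,0,this_study,results:albopunctata-group
"Boana faber",Boana,"B. faber",1,0,3M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,terminal,1,0,this_study,results:faber-pellucens-groups
"Boana pellucens",Boana,"B. pellucens",1,0,2M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,interstitial,1,0,this_study,results:faber-pellucens-groups
"Boana cinerascens",Boana,"B. punctata",1,0,7M1U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,interstitial,1,0,this_study,results:punctata-group
"Boana punctata",Boana,"B. punctata",1,0,2F,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,,1,0,this_study,results:punctata-group
"Boana boans",Boana,"B. semilineata",1,0,2M1U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,7,interstitial,1,0,this_study,results:semilineata-group
"Boana cf. semilineata",Boana,"B. semilineata",1,0,1M1U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,7,interstitial,1,0,this_study,results:semilineata-group
"Boana wavrini",Boana,"B. semilineata",1,0,1M2U,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,interstitial,1,0,this_study,results:semilineata-group
"Boana albonigra",Boana,"B. pulchella",1,0,1F2M,"Ag-NORs;C-bands;DAPI/CMA3",12,11,interstitial,1,0,this_study,results:pulchella-group
"Boana bischoffi",Boana,"B. pulchella",1,0,1M,"Ag-NORs;C-bands",12,11,interstitial,1,0,this_study,results:pulchella-group
"Boana caingua",Boana,"B. pulchella",1,0,1F12M,"Ag-NORs;C-bands;DAPI/CMA3",12,12,interstitial,1,0,this_study,results:pulchella-group
"Boana cipoensis",Boana,"B. pulchella",1,0,4M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,1,terminal,1,0,this_study,results:pulchella-group
"Boana cordobae",Boana,"B. pulchella",1,0,2F9M,"Ag-NORs;C-bands;DAPI/CMA3",12,11,terminal,1,0,this_study,results:pulchella-group
"Boana curupi",Boana,"B. pulchella",1,0,6M,"Ag-NORs;C-bands;DAPI/CMA3",12,1,terminal,1,0,this_study,results:pulchella-group
"Boana marianitae",Boana,"B. pulchella",1,0,2M,"Ag-NORs;C-bands;DAPI/CMA3",12,11,interstitial,1,0,this_study,results:pulchella-group
"Boana pulchella",Boana,"B. pulchella",1,0,3F34M1J,"Ag-NORs;C-bands;DAPI/CMA3",12,12,terminal,1,0,this_study,results:pulchella-group
"Boana riojana",Boana,"B. pulchella",1,0,6F8M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,11,interstitial,1,0,this_study,results:pulchella-group
"Boana stellae",Boana,"B. pulchella",1,0,1F8M,"Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",12,1,terminal,1,0,this_study,results:pulchella-group
"Boana pulchella (LGE 11504)",Boana,"B. pulchella",1,1,1M,"Ag-NORs;C-bands",12,12,terminal,1,0,this_study,results:pulchella-group
"Myersiohyla",Myersiohyla,,0,0,,,,,,0,0,literature,discussion:basic-number
"Hyloscirtus armatus",Hyloscirtus,"H. armatus",0,0,,,12,,,0,0,literature,discussion:basic-number
"Bokermannohyla alvarengai",Bokermannohyla,,0,0,,,12,4,,0,0,literature,discussion:nor-location
"Bokermannohyla ibitiguara",Bokermannohyla,,0,0,,,12,1,,0,0,literature,discussion:nor-location
"Aplastodiscus perviridis",Aplastodiscus,"A. perviridis",0,0,,,12,11,,1,0,literature,discussion:nor-location
"Aplastodiscus cochranae",Aplastodiscus,"A. perviridis",0,0,,,12,11,,1,0,literature,discussion:nor-location
"Aplastodiscus albosignatus",Aplastodiscus,"A. albosignatus",0,0,,,10,9,,1,0,literature,discussion:nor-location
"Aplastodiscus callipygius",Aplastodiscus,"A. albosignatus",0,0,,,,9,,1,0,literature,discussion:nor-location
"Aplastodiscus leucopygius",Aplastodiscus,"A. albosignatus",0,0,,,9,9,,1,0,literature,discussion:nor-location
"Aplastodiscus albofrenatus",Aplastodiscus,"A. albofrenatus",0,0,,,11,6,,1,0,literature,discussion:nor-location
"Aplastodiscus arildae",Aplastodiscus,"A. albofrenatus",0,0,,,11,11,,1,0,literature,discussion:nor-location
"Aplastodiscus ehrhardti",Aplastodiscus,"A. albofrenatus",0,0,,,11,6,,1,0,literature,discussion:nor-location
"Aplastodiscus eugenioi",Aplastodiscus,"A. albofrenatus",0,0,,,11,6,,1,0,literature,discussion:nor-location
"Boana albopunctata",Boana,"B. albopunctata",0,0,,,11,8,,1,0,literature,discussion:albopunctata-group
"Boana fasciata",Boana,"B. albopunctata",0,0,,,12,,,0,1,literature,discussion:albopunctata-group
"Boana prasina",Boana,"B. pulchella",0,0,,,,9;12,,1,0,literature,discussion:nor-location
"Boana joaquini",Boana,"B. pulchella",0,0,,,,1,,1,0,literature,discussion:nor-location
"Boana semiguttata",Boana,"B. pulchella",0,0,,,,1,,1,0,literature,discussion:nor-location
"Boana pombali",Boana,"B. semilineata",0,0,,,,7,,0,0,literature,discussion:nor-location
"Boana geographica",Boana,"B. semilineata",0,0,,,,1,centromeric,0,0,literature,discussion:nor-location
"Boana semilineata",Boana,"B. semilineata",0,0,,,,7,,1,0,literature,discussion:nor-location
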