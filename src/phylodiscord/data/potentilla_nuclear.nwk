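((Dasiphora_fruticosa:1,Fragaria_vesca:1,Rosa_majalis:1,Sanguisorba_officinalis:1,Comarum_palustre:1,Sibbaldia_cuneata:1,Chamaerhodos_mongholica:1,(Potentilla_lignosa:1,(Potentilla_anserina:1,Potentilla_microphylla:1,(Potentilla_stenophylla:1,Potentilla_peduncularis:1)1.0:1)1.0:1)1.0:1)0.61:1,(((Potentilla_articulata:1,Potentilla_biflora:1)1.0:1,Potentilla_alba:1,Potentilla_alchemilloides:1,Potentilla_caulescens:1,Potentilla_grammopetala:1,Potentilla_micrantha:1,Potentilla_nitida:1,Potentilla_sterilis:1)0.99:1,((Potentilla_dickinsii:1,(Potentilla_fragarioides:1,Potentilla_stolonifera:1)1.0:1)1.0:1,((Potentilla_erecta:1,Potentilla_indica:1,Potentilla_reptans:1)1.0:1,((Potentilla_norvegica:1,((Horkelia_californica:1,Horkelia_bolanderi:1)0.88:1,Horkelia_fusca:1,Horkeliella_purpurascens:1,Ivesia_gordonii:1,Ivesia_kingii:1,Comarella_multifoliolata:1)1.0:1)0.98:1,(Potentilla_argentea:1,Potentilla_nepalensis:1,Potentilla_argyrophylla:1,Potentilla_atrosanguinea:1,Potentilla_pimpinelloides:1,Potentilla_hyparctica:1,Potentilla_crebridens:1,Potentilla_gracilis:1,Potentilla_hippiana:1,Potentilla_nivea:1,Potentilla_tollii:1,Potentilla_flabellifolia:1,Potentilla_gorodkovii:1,Potentilla_subvahliana:1,Potentilla_uniflora:1,Potentilla_fragiformis:1,Potentilla_grandiflora:1,Potentilla_montenegrina:1,Potentilla_thurberi:1,Potentilla_elegans:1,(Potentilla_crantzii:1,Potentilla_recta:1,Potentilla_thuringiaca:1,(Potentilla_tanacetifolia:1,Potentilla_kurdica:1,Potentilla_chrysantha:1,Potentilla_caucasica:1,Potentilla_tabernaemontani:1,Potentilla_neumanniana:1)1.0:1)0.96:1,(Potentilla_multifida:1,Potentilla_pedersenii:1,Potentilla_rubricaulis:1)1.0:1,(Potentilla_villosa:1,Potentilla_pulvinaris:1)1.0:1,(Potentilla_chinensis:1,Potentilla_discolor:1)0.97:1)1.0:1)1.0:1)0.98:1)0.94:1)1.0:1);
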