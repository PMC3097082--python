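taxon	ploidy_string	clade	style_shape	anther_shape
Dasiphora_fruticosa		Outgroup
Fragaria_vesca		Outgroup
Rosa_majalis		Outgroup
Sanguisorba_officinalis		Outgroup
Comarum_palustre		Outgroup	N
Sibbaldia_cuneata		Outgroup
Chamaerhodos_mongholica		Outgroup
Potentilla_anserina	4x, 5x, 6x	A	L	B
Potentilla_microphylla	2x, 4x	A	L	D
Potentilla_peduncularis	4x	A	L	B
Potentilla_stenophylla		A	L	B
Potentilla_lignosa		A	N	C
Potentilla_articulata		B	N
Potentilla_biflora	2x	B	N	B
Potentilla_alba	4x	B	N	C
Potentilla_alchemilloides	2x	B	N	C
Potentilla_caulescens	2x, 6x	B	N	C
Potentilla_clusiana	2x, 6x	B	N	C
Potentilla_grammopetala		B	N	C
Potentilla_micrantha	2x	B	N	C
Potentilla_nitida	6x	B	N	C
Potentilla_sterilis	4x	B	N	A
Potentilla_dickinsii	2x	C	N	C
Potentilla_fragarioides	2x	C	G	A
Potentilla_stolonifera		C	G	B
Potentilla_erecta	2x, 3x, 4x, 5x, aneuploids	D	G	A
Potentilla_indica	10x, 12x	D	G	B
Potentilla_reptans	4x	D	G	A
Comarella_multifoliolata		E	C	B
Horkelia_bolanderi		E	C
Horkelia_californica	4x	E	C	C
Horkelia_fusca	4x	E	C	B
Horkeliella_purpurascens		E	C	B
Ivesia_gordonii		E	C	B
Ivesia_kingii		E	C	B
Potentilla_norvegica	8x, 10x	F	C	D
Potentilla_argentea	2x, 4x, 5x, 6x, 8x, 12x?	F	C	A
Potentilla_nepalensis		F	C	C
Potentilla_argyrophylla		F	C	B
Potentilla_atrosanguinea		F	C	C
Potentilla_caucasica		F	C	C
Potentilla_chrysantha	4x, 6x, 8x	F	C	B
Potentilla_kurdica		F	C
Potentilla_pimpinelloides	2x, 10x	F	C	A
Potentilla_recta	2x, 4x, 5x, 6x, 8x	F	C	A
Potentilla_tanacetifolia	4x	F	C	A
Potentilla_thuringiaca	6x, 8x	F	C	A
Potentilla_crantzii	4x, 5x, 6x, 7x, aneuploids	F	G	B
Potentilla_neumanniana	2x, 4x	F	G	A
Potentilla_tabernaemontani	4x, 5x, 6x, 7x, 8x, 9x, 10x, 12x, aneuploids	F	G	A
Potentilla_hyparctica	6x	F	G	B
Potentilla_chinensis	2x	F	C	C
Potentilla_crebridens	4x	F	C	A
Potentilla_discolor		F	C	A
Potentilla_gracilis	12x, 13x	F	C	C
Potentilla_hippiana	12x	F	C	A
Potentilla_nivea	2x, 3x, 4x, 5x, 6x, 7x, 8x, 10x	F	C	B
Potentilla_tollii		F	C	B
Potentilla_flabellifolia		F	C	C
Potentilla_gorodkovii		F	C	B
Potentilla_pulvinaris		F	C	B
Potentilla_subvahliana	4x	F	C	B
Potentilla_uniflora	2x, 3x, 4x, 6x	F	C	B
Potentilla_villosa	2x	F	C	B
Potentilla_fragiformis	6x, 8x	F	C
Potentilla_grandiflora	(2x), 4x, (6x)	F	C	B
Potentilla_montenegrina	4x, 6x	F	C	A
Potentilla_multifida	(2x), 4x, (6x)	F	C	C
Potentilla_pedersenii		F	C	B
Potentilla_rubricaulis	8x?	F	C	B
Potentilla_thurberi		F	C	A
Potentilla_elegans	2x, 4x	F	G	B
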