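taxon	family	order	rank	nb_grassland	nb_shrubs	nb_forest	reads_grassland	reads_shrubs	reads_forest
Acalles dubius	Curculionidae	Coleoptera	species	1	0	0	39	0	0
Acrididae	Acrididae	Orthoptera	family	1	0	0	1035	0	0
Agrilus olivicolor	Buprestidae	Coleoptera	species	0	1	0	0	148	0
Aphelinus chaonia	Aphelinidae	Hymenoptera	species	0	1	0	0	18564	0
Apionidae	Apionidae	Coleoptera	family	1	0	0	352	0	0
Athalia	Athaliidae	Hymenoptera	genus	2	0	0	497	0	0
Athaliidae	Athaliidae	Hymenoptera	family	1	0	0	52	0	0
Baetis	Baetidae	Ephemeroptera	genus	1	0	0	43	0	0
Braconidae	Braconidae	Hymenoptera	family	1	4	1	15	363	86
Caeciliusidae	Caeciliusidae	Psocodea	family	1	1	2	44	108	37
Carabidae	Carabidae	Coleoptera	family	0	1	0	0	413	0
Cerambycidae	Cerambycidae	Coleoptera	family	0	1	0	0	1437	0
Chaetocnema hortensis	Chrysomelidae	Coleoptera	species	3	1	0	272	411	0
Chironomidae	Chironomidae	Diptera	family	0	0	1	0	0	323
Chrysomelidae	Chrysomelidae	Coleoptera	family	1	1	0	120	979	0
Cicadellidae	Cicadellidae	Hemiptera	family	3	0	0	210	0	0
Coleoptera	-	Coleoptera	order	3	3	3	2108	708	10218
Corynoptera perpusilla	Sciaridae	Diptera	species	2	0	0	5088	0	0
Corynoptera tetrachaeta	Sciaridae	Diptera	species	1	0	0	232	0	0
Crepidodera aurata	Chrysomelidae	Coleoptera	species	0	1	0	0	171	0
Culex	Culicidae	Diptera	genus	1	0	0	141	0	0
Curculio glandium	Curculionidae	Coleoptera	species	0	0	1	0	0	241
Curculionidae	Curculionidae	Coleoptera	family	1	2	1	84	1167	268
Dasytes	Melyridae	Coleoptera	genus	0	1	1	0	242	20128
Diptera	-	Diptera	order	2	0	0	9854	0	0
Ecdyonurus	Heptageniidae	Ephemeroptera	genus	1	0	0	64	0	0
Ectopsocidae	Ectopsocidae	Psocodea	family	1	2	3	10	170	8517
Ectopsocus	Ectopsocidae	Psocodea	genus	1	1	0	341	10814	0
Ectopsocus meridionalis	Ectopsocidae	Psocodea	species	3	3	3	921	8559	392
Entomobryidae	Entomobryidae	Entomobryomorpha	family	5	0	0	267	0	0
Entomobryomorpha	-	Entomobryomorpha	order	6	0	2	62586	0	535
Forficula auricularia	Forficulidae	Dermaptera	species	3	0	0	4912	0	0
Galeruca luctuosa	Chrysomelidae	Coleoptera	species	0	1	0	0	61	0
Graphopsocus	Psocidae	Psocodea	genus	0	0	1	0	0	12
Graphopsocus cruciatus	Psocidae	Psocodea	species	0	2	4	0	26951	11633
Halyomorpha halys	Pentatomidae	Hemiptera	species	1	0	0	42	0	0
Hemiptera	-	Hemiptera	order	2	0	3	7715	0	43051
Heptageniidae	Heptageniidae	Ephemeroptera	family	1	0	0	2113	0	0
Hymenoptera	-	Hymenoptera	order	2	3	0	151	14413	0
Ischnopterapion virens	Apionidae	Coleoptera	species	1	0	0	186	0	0
Issus kabylicus	Issidae	Hemiptera	species	0	1	0	0	40	0
Laothoe	Sphingidae	Lepidoptera	genus	0	1	0	0	1285	0
Laothoe populi	Sphingidae	Lepidoptera	species	0	1	0	0	62	0
Lepidoptera	-	Lepidoptera	order	1	0	0	18	0	0
Leptophyes punctatissima	Tettigoniidae	Orthoptera	species	0	0	1	0	0	125
Leuctra fusca	Leuctridae	Plecoptera	species	2	0	0	3651	0	0
Liorhyssus hyalinus	Rhopalidae	Hemiptera	species	1	0	0	24	0	0
Longitarsus luridus	Chrysomelidae	Coleoptera	species	1	0	0	26	0	0
Longitarsus pratensis	Chrysomelidae	Coleoptera	species	3	0	0	143	0	0
Longitarsus salviae	Chrysomelidae	Coleoptera	species	3	0	0	210	0	0
Macroglossum stellatarum	Sphingidae	Lepidoptera	species	1	0	0	33	0	0
Melyridae	Melyridae	Coleoptera	family	0	0	1	0	0	86
Neuroptera	-	Neuroptera	order	1	0	0	1555	0	0
Nipponomeconema	Tettigoniidae	Orthoptera	genus	1	0	0	109	0	0
Noctua pronuba	Noctuidae	Lepidoptera	species	0	1	0	0	28	0
Noctuidae	Noctuidae	Lepidoptera	family	0	1	0	0	565	0
Ocypus olens	Staphylinidae	Coleoptera	species	1	0	0	108	0	0
Oscinella pusilla	Chloropidae	Diptera	species	1	0	0	31	0	0
Peripsocidae	Peripsocidae	Psocodea	family	0	0	1	0	0	1928
Peripsocus subfasciatus	Peripsocidae	Psocodea	species	0	2	0	0	245	0
Psocidae	Psocidae	Psocodea	family	0	0	1	0	0	104
Psocodea	-	Psocodea	order	0	2	1	0	1630	2251
Psychodidae	Psychodidae	Diptera	family	2	3	1	105	491	11
Pyrausta despicata	Crambidae	Lepidoptera	species	1	0	0	40	0	0
Pyrrhidium sanguineum	Cerambycidae	Coleoptera	species	2	0	0	113	0	0
Rhopalosiphum padi	Aphididae	Hemiptera	species	0	1	0	0	39	0
Rhynchaenus quercus	Curculionidae	Coleoptera	species	0	0	1	0	0	98
Sciaridae	Sciaridae	Diptera	family	2	1	1	72	16	221
Sphingidae	Sphingidae	Lepidoptera	family	0	1	0	0	86	0
Tettigonia viridissima	Tettigoniidae	Orthoptera	species	1	0	0	21	0	0
Thripidae	Thripidae	Thysanoptera	family	4	0	0	833	0	0
Thysanoptera	-	Thysanoptera	order	2	0	0	3112	0	0
Trichadenotecnum sexpunctatum	Psocidae	Psocodea	species	0	2	0	0	518	0
Valenzuela	Psocidae	Psocodea	genus	1	1	0	11	199	0
Vespula vulgaris	Vespidae	Hymenoptera	species	0	1	0	0	13	0
Xyleborus monographus	Curculionidae	Coleoptera	species	0	0	1	0	0	603
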