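# FoxJ1 survey evidence: reverse-BLAST and phylogeny calls for the 60 Fox-domain
# proteins identified across opisthokont proteomes (paralogs as separate rows).
# Cell mapping used by the loader: phylo_* == 'FoxJ1'/'Foxj1' -> grouped with the
# target subfamily; 'Sister to ...'/'Unresolved' -> not grouped; empty -> analysis
# absent. Full-length phylogeny was run only for the fungal proteins.
candidate_id	organism	supergroup	group	phylum	paralog_index	evalue	reverse_blast	annotation	phylo_domain	bootstrap_domain	phylo_full	bootstrap_full
Trichoplax_adhaerens	Trichoplax adhaerens	Opisthokonta	Animalia	Placozoa	1	8E-38	FoxJ1	Hypothetical protein TRIADDRAFT_17444	FoxJ1	99		
Hydra_magnipapillata	Hydra magnipapillata	Opisthokonta	Animalia	Cnidaria	1	9E-32	FoxJ1	Similar to FoxJ1	FoxJ1	49		
Nematostella_vectensis	Nematostella vectensis	Opisthokonta	Animalia	Cnidaria	1	3E-39	FoxJ1	Predicted protein	FoxJ1	99		
Capitella_sp_I	Capitella sp. I	Opisthokonta	Animalia	Annelida	1	4E-47	FoxJ1	e_gw1.802.18.1	FoxJ1	99		
Lottia_gigantea	Lottia gigantea	Opisthokonta	Animalia	Mollusca	1	2E-44	FoxJ1	Fgenesh2_pg.C_sca_5000409	FoxJ1	99		
Strongylocentrotus_purpuratus	Strongylocentrotus purpuratus	Opisthokonta	Animalia	Echinodermata	1	1E-37	FoxJ1	FoxJ1	FoxJ1	100		
Daphnia_pulex	Daphnia pulex	Opisthokonta	Animalia	Arthropoda	1	9E-36	FoxJ1	Hypothetical protein	FoxJ1	97		
Tribolium_castaneum	Tribolium castaneum	Opisthokonta	Animalia	Arthropoda	1	2E-32	FoxJ1	Hypothetical protein	FoxJ1	99		
Pediculus_humanus_corporis	Pediculus humanus corporis	Opisthokonta	Animalia	Arthropoda	1	1E-34	FoxJ1	Forkhead protein, putative	FoxJ1	99		
Branchiostoma_floridae	Branchiostoma floridae	Opisthokonta	Animalia	Chordata	1	1E-37	FoxJ1	Hypothetical protein	FoxJ1	99		
Danio_rerio_p1	Danio rerio	Opisthokonta	Animalia	Chordata	1	3E-50	FoxJ1	FoxJ1a/FoxJ1b	FoxJ1	100		
Danio_rerio_p2	Danio rerio	Opisthokonta	Animalia	Chordata	2	1E-43	FoxJ1	FoxJ1a/FoxJ1b	FoxJ1	99		
Tetraodon_nigroviridis_p1	Tetraodon nigroviridis	Opisthokonta	Animalia	Chordata	1	1E-47	FoxJ1	Unnamed protein product	FoxJ1	99		
Tetraodon_nigroviridis_p2	Tetraodon nigroviridis	Opisthokonta	Animalia	Chordata	2	6E-41	FoxJ1	Unnamed protein product	FoxJ1	99		
Fugu_rubripes_p1	Fugu rubripes	Opisthokonta	Animalia	Chordata	1	1E-58	FoxJ1	e_gw2.514.3.1/e_gw2.3.885.1	FoxJ1	100		
Fugu_rubripes_p2	Fugu rubripes	Opisthokonta	Animalia	Chordata	2	4.16E-51	FoxJ1	e_gw2.514.3.1/e_gw2.3.885.1	FoxJ1	99		
Xenopus_tropicalis_p1	Xenopus tropicalis	Opisthokonta	Animalia	Chordata	1	5E-50	FoxJ1	FoxJ1/FoxJ1.2	FoxJ1	100		
Xenopus_tropicalis_p2	Xenopus tropicalis	Opisthokonta	Animalia	Chordata	2	4E-41	FoxJ1	FoxJ1/FoxJ1.2	FoxJ1	99		
Gallus_gallus	Gallus gallus	Opisthokonta	Animalia	Chordata	1	1E-49	FoxJ1	FoxJ1	FoxJ1	100		
Homo_sapiens	Homo sapiens	Opisthokonta	Animalia	Chordata	1	5E-51	FoxJ1	FoxJ1	FoxJ1	100		
Mus_musculus	Mus musculus	Opisthokonta	Animalia	Chordata	1	3E-51	FoxJ1	FoxJ1	FoxJ1	100		
Rattus_norvegicus	Rattus norvegicus	Opisthokonta	Animalia	Chordata	1	1E-51	FoxJ1	FoxJ1	FoxJ1	100		
Bos_taurus	Bos taurus	Opisthokonta	Animalia	Chordata	1	1E-51	FoxJ1	FoxJ1	FoxJ1	100		
Canis_familiaris	Canis familiaris	Opisthokonta	Animalia	Chordata	1	1E-50	FoxJ1	FoxJ1	FoxJ1	100		
Pongo_pygmaeus	Pongo pygmaeus	Opisthokonta	Animalia	Chordata	1	3.6E-75	FoxJ1	FoxJ1	FoxJ1	100		
Cavia_porcellus	Cavia porcellus	Opisthokonta	Animalia	Chordata	1	2.8E-75	FoxJ1	FoxJ1	FoxJ1	100		
Erinaceus_europaeus	Erinaceus europaeus	Opisthokonta	Animalia	Chordata	1	4.3E-58	FoxJ1	FoxJ1	FoxJ1	100		
Loxodonta_africana	Loxodonta africana	Opisthokonta	Animalia	Chordata	1	3.6E-75	FoxJ1	FoxJ1	FoxJ1	100		
Gorilla_gorilla	Gorilla gorilla	Opisthokonta	Animalia	Chordata	1	4.4E-75	FoxJ1	FoxJ1	FoxJ1	100		
Microcebus_murinus	Microcebus murinus	Opisthokonta	Animalia	Chordata	1	3.6E-68	FoxJ1	FoxJ1	FoxJ1	100		
Myotis_lucifugus	Myotis lucifugus	Opisthokonta	Animalia	Chordata	1	4.7E-71	FoxJ1	FoxJ1	FoxJ1	100		
Ochotona_princeps	Ochotona princeps	Opisthokonta	Animalia	Chordata	1	2.4E-75	FoxJ1	FoxJ1	FoxJ1	100		
Procavia_capensis	Procavia capensis	Opisthokonta	Animalia	Chordata	1	3E-74	FoxJ1	FoxJ1	FoxJ1	100		
Pteropus_vampyrus	Pteropus vampyrus	Opisthokonta	Animalia	Chordata	1	6.1E-70	FoxJ1	FoxJ1	FoxJ1	100		
Tupaia_belangeri	Tupaia belangeri	Opisthokonta	Animalia	Chordata	1	1.5E-46	FoxJ1	FoxJ1	FoxJ1	100		
Felis_catus	Felis catus	Opisthokonta	Animalia	Chordata	1	1.8E-59	FoxJ1	FoxJ1	FoxJ1	100		
Equus_caballus	Equus caballus	Opisthokonta	Animalia	Chordata	1	8E-52	FoxJ1	FoxJ1	FoxJ1	100		
Macaca_mulatta	Macaca mulatta	Opisthokonta	Animalia	Chordata	1	8E-52	FoxJ1	FoxJ1	FoxJ1	100		
Tursiops_truncatus	Tursiops truncatus	Opisthokonta	Animalia	Chordata	1	2.5E-74	FoxJ1	FoxJ1	FoxJ1	100		
Monodelphis_domestica	Monodelphis domestica	Opisthokonta	Animalia	Chordata	1	9E-52	FoxJ1	FoxJ1	FoxJ1	100		
Ornithorhynchus_anatinus	Ornithorhynchus anatinus	Opisthokonta	Animalia	Chordata	1	6E-51	FoxJ1	FoxJ1	FoxJ1	100		
Oryctolagus_cuniculus	Oryctolagus cuniculus	Opisthokonta	Animalia	Chordata	1	1E-51	FoxJ1	FoxJ1	FoxJ1	100		
Pan_troglodytes	Pan troglodytes	Opisthokonta	Animalia	Chordata	1	2E-51	FoxJ1	FoxJ1	FoxJ1	100		
Taeniopygia_guttata	Taeniopygia guttata	Opisthokonta	Animalia	Chordata	1	3E-38	FoxJ1	Similar to FoxJ1	FoxJ1	99		
Aspergillus_clavatus	Aspergillus clavatus	Opisthokonta	Fungi	Ascomycota	1	8E-27	FoxJ1	Forkhead transcription factor Fkh1/2, putative	Sister to FoxJ1-J3, FoxK1-K2		Sister to FoxJ2 and FoxJ3	44
Aspergillus_niger	Aspergillus niger	Opisthokonta	Fungi	Ascomycota	1	1E-27	FoxJ1	Forkhead transcription factor Fkh1/2	Sister to FoxJ1-J3, FoxK1-K2		Sister to FoxJ2 and FoxJ3	60
Candida_glabrata	Candida glabrata	Opisthokonta	Fungi	Ascomycota	1	1E-25	FoxJ1	Hypothetical protein	Sister to FoxK1-K2		Sister to FoxP1-P4, FoxR1-R2	51
Eremothecium_gossypii	Eremothecium gossypii	Opisthokonta	Fungi	Ascomycota	1	5E-26	FoxJ1	AER369Cp	FoxJ1	31	Foxj1	66
Saccharomyces_cerevisiae	Saccharomyces cerevisiae	Opisthokonta	Fungi	Ascomycota	1	2E-24	FoxJ1	Forkhead protein	Sister to FoxK1-K2		Foxj1	48
Schizosaccharomyces_pombe	Schizosaccharomyces pombe	Opisthokonta	Fungi	Ascomycota	1	7E-25	FoxD2	Fork head transcription factor Fhl1	Foxj1	52	Unresolved	
Aspergillus_oryzae	Aspergillus oryzae	Opisthokonta	Fungi	Ascomycota	1	3E-27	FoxJ1	Forkhead transcription factor Fkh1/2	Sister to FoxJ1-J3, FoxK1-K2		Sister to FoxJ2 and FoxJ3	47
Aspergillus_terreus	Aspergillus terreus	Opisthokonta	Fungi	Ascomycota	1	6E-27	FoxJ1	Forkhead box protein C2	Sister to FoxJ1-J3, FoxK1-K2		Sister to FoxJ2 and FoxJ3	46
Coccidioides_immitis	Coccidioides immitis	Opisthokonta	Fungi	Ascomycota	1	2E-25	FoxJ1	Hypothetical protein CIMG_03727	FoxJ1	32	Sister to FoxJ2 and FoxJ3	47
Coccidioides_posadasii	Coccidioides posadasii	Opisthokonta	Fungi	Ascomycota	1	3E-25	FoxJ1	Fork head domain containing protein	FoxJ1	32	Foxj1	53
Schizosaccharomyces_japonicus	Schizosaccharomyces japonicus	Opisthokonta	Fungi	Ascomycota	1	3E-23	FoxJ1	Fork head transcription factor 1	Sister to FoxO1, O3, O4, O6		Sister to FoxP1-P4, FoxR1-R2	59
Stagonospora_nodorum	Stagonospora nodorum	Opisthokonta	Fungi	Ascomycota	1	9E-23	FoxJ1	Hypothetical protein SNOG_11882	Sister to FoxJ1-J3, FoxK1-K2		Unresolved	
Laccaria_bicolor	Laccaria bicolor	Opisthokonta	Fungi	Basidiomycota	1	4E-15	FoxJ1	Predicted protein	Sister to FoxP1-P4		Foxh1	52
Encephalitozoon_cuniculi	Encephalitozoon cuniculi	Opisthokonta	Fungi	Microsporidia	1	2E-26	FoxJ1	Transcription factor (forkhead domain)	Sister to FoxJ1-J3, FoxK1-K2		Sister to FoxJ2 and FoxJ3	39
Allomyces_macrogynus	Allomyces macrogynus	Opisthokonta	Fungi	Blastocladiomycota	1	4.01858E-25	FoxJ1	forkhead box J3	Sister to FoxJ2-J3		Sister to FoxP1-P4, FoxR1-R2	97
Monosiga_brevicollis	Monosiga brevicollis	Opisthokonta	Choanozoa	Choanozoa	1	2.95E-29	FoxJ1	fgenesh2_pg.scaffold_5000329	Sister to FoxJ1-J3, FoxK1-K2			
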