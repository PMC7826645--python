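fraction_id	transcript_accession	trimmed	mature_kda	hit_accession	percent_identity	product_name	organism
# Published fraction -> transcript mapping for the R. ferrugineus hemolymph
# study: transcript accession(s) per fraction, 5'-trimmed flag, reported
# mature mass (kDa), best database hit and its identity / product / organism.
# Used as an input table (e.g. for family tallies) and as the expected
# mapping when the NCBI records have been fetched into a local cache.
1.1	JR492050.1	no	11.95	XP_019761640.1	55.41	Attacin-B-like protein	Dendroctonus ponderosae
1.1	JR485705.1	yes	12.58	XP_019761640.1	55.41	Attacin-B-like protein	Dendroctonus ponderosae
1.1	JR485629.1	yes	12.27	XP_019761640.1	55.41	Attacin-B-like protein	Dendroctonus ponderosae
2.1	JR471060.1	no	6.90	ABZ80665.1	77.11	Defensin	Sitophilus zeamais
3.1	JR470869.1	no	13.17	APG79375.1	74.44	Pheromone-binding protein 14	Cyrtotrachelus buqueti
3.2	JR484067.1	no	14.09	ATU47279.1	100.00	Odorant-binding protein 9	Rhynchophorus ferrugineus
3.3	JR491618.1	no	7.25	ABZ80665.1	55.95	Defensin	Sitophilus zeamais
3.3	JR477230.1	yes	6.20	ABZ80665.1	85.42	Defensin	Sitophilus zeamais
4.1	JR484067.1	no	14.09	ATU47279.1	100.00	Odorant-binding protein 9	Rhynchophorus ferrugineus
4.2	JR486084.1	no	4.97	ABZ80668.1	73.91	Hypothetical antimicrobial peptide	Sitophilus zeamais
4.3	JR489305.1	no	12.84	APG79371.1	79.26	Pheromone-binding protein 10	Cyrtotrachelus buqueti
4.4	JR489305.1	no	12.84	APG79371.1	79.26	Pheromone-binding protein 10	Cyrtotrachelus buqueti
4.5	JR472381.1	no	13.84	AMK48596.1	100.00	Odorant-binding protein	Rhynchophorus ferrugineus
4.6	JR472381.1	no	13.84	AMK48596.1	100.00	Odorant-binding protein	Rhynchophorus ferrugineus
4.7	JR484067.1	no	14.09	ATU47279.1	100.00	Odorant-binding protein 9	Rhynchophorus ferrugineus
4.8	JR489305.1	no	12.84	APG79371.1	79.26	Pheromone-binding protein 10	Cyrtotrachelus buqueti
4.9	JR489305.1	no	12.84	APG79371.1	79.26	Pheromone-binding protein 10	Cyrtotrachelus buqueti
5.1	JR482588.1	no	12.41	ATU47278.1	100.00	Odorant-binding protein 28	Rhynchophorus ferrugineus
5.2	JR482588.1	no	12.41	ATU47278.1	100.00	Odorant-binding protein 28	Rhynchophorus ferrugineus
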