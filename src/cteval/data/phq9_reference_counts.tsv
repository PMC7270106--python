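# Published per-category transcription confusion counts for the PHQ-9
# keyword lexicon, from a study of cloud ASR on 100 psychotherapy
# sessions (reference data; sensitivity/PPV are always recomputed).
# columns: category_id	n_positives	TP	FN	FP
1	169	127	42	38
2	74	63	11	12
3	114	85	29	19
4	143	115	28	22
5	5	3	2	0
6	405	336	69	56
7	11	9	2	0
8	39	28	11	13
9	103	86	17	18
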