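# Published normalized decolorization percentages (mean of three replicates,
# % of wild type) for the 20 screen-confirmed transposon mutants, with the
# gene reported interrupted by the best reference hit (NA = no similarity
# found / additional band without its own decolorization value).
mutant_id	normalized_decol_pct	gene
1494	3.1	arsC
1533	50.3	relA
1454	59.5	trmM
1534	46.2	trmM
3954	53.5	trmM
3047	42.1	trmM
3968	58.8	plsY
3997	53.3	trmM
1922	49.8	trmM
3988	38.04	arsC
1015	64.76	arsC
1240	64.04	glnE
2995	61.7	arsC
1942	65	NA
3018	32.3	NA
266	127.1	NA
2474	122.3	trmM
2691	118.3	trmM
2171	114.6	NA
268	110.7	NA
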