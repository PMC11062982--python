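# Published repetition histogram of focal-gene profile neighbors across a
# 50-dataset compendium: count value <TAB> number of genes at that count.
# The nine-repetition bin is absent in the source and treated as zero genes.
repetitions	n_genes
1	4345
2	1280
3	553
4	229
5	77
6	28
7	5
8	1
10	1
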