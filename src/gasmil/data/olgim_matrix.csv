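# OLGIM staging matrix: rows = antrum intestinal-metaplasia score 0-3,
# columns = corpus IM score 0-3, cell = stage 0-4. Same lattice as OLGA.
antrum_score,corpus_0,corpus_1,corpus_2,corpus_3
0,0,1,2,2
1,1,1,2,3
2,2,2,3,4
3,3,3,4,4
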