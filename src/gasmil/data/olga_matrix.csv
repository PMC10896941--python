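# OLGA staging matrix: rows = antrum atrophy score 0-3 (incisura included in
# the antrum compartment), columns = corpus atrophy score 0-3, cell = stage 0-4.
antrum_score,corpus_0,corpus_1,corpus_2,corpus_3
0,0,1,2,2
1,1,1,2,3
2,2,2,3,4
3,3,3,4,4
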