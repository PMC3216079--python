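hip,lateral_transgluteal,mis_anterior,mis_anterolateral,mis_2incision,mis_posterior
1,6,35,27,29,22
2,22,0,14,24,0
3,16,0,6,40,18
4,32,0,23,26,0
5,40,0,18,14,22
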