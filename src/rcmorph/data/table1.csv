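specimen_id,rc_length,diam_base,diam_45,diam_90,rc_volume
1,14.02,0.133,0.291,0.435,1.182
2,14.73,0.100,0.366,0.498,1.376
3,14.28,0.109,0.395,0.464,1.087
4,14.61,0.060,0.442,0.430,1.392
5,14.22,0.116,0.432,0.495,1.668
6,15.08,0.143,0.382,0.464,1.746
7,14.91,0.103,0.482,0.590,1.246
8,14.58,0.109,0.494,0.567,2.315
9,14.27,0.122,0.468,0.444,2.012
10,14.98,0.096,0.519,0.637,2.150
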