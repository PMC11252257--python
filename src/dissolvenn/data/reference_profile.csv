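time_h,release_pct
1,3
2,7
4,15
6,24
8,33
10,43
12,53
16,68
20,78
24,83
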