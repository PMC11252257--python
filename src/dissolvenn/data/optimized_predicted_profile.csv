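time_h,release_pct
1,3
2,7
4,18
6,26
8,32
10,43
12,55
16,70
20,76
24,82
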