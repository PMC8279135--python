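actual,predicted
1,-307.18
-2,636.16
3,-469.99
-4,671.53
5,-180.55
-6,838.23
7,-979.18
-8,455.16
9,-8.32
-10,366.80
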