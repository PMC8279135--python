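actual,predicted
90.317571,45.02545
40.336481,43.75556
5.619065,41.18064
44.529437,42.09511
71.192687,44.85773
32.036909,44.09390
6.977097,41.58419
66.425010,43.25487
95.971166,44.27568
5.756337,49.75250
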