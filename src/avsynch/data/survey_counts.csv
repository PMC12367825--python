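device,bin,percent,n_responses
AV,<5,11,104
AV,5-10,29,104
AV,11-20,30,104
AV,>20,30,104
AV2,<5,51,98
AV2,5-10,35,98
AV2,11-20,10,98
AV2,>20,4,98
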