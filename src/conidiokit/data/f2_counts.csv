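cross,wt,wrap,bulky
AxB,103,167,126
BxC,142,86,58
AxC,170,108,88
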