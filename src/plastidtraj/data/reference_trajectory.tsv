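point	plastid_count	cumulative_correction
basal	8	1.0
peak	72	2.0
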