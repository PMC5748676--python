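# Published defaults; edit to override.
# consensus_threshold = 0.90
# group1_identity = 0.95
# residual_identity = 0.80
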