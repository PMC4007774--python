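primitive_a	primitive_b	similarity
endocrine-system	thyroid	0.85
disease	inflammation	0.35
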