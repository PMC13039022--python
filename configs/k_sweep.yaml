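# codebook-size sweep
sweep: codebook_k
values: [16, 32, 64, 128, 256]
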