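# commitment-weight sweep for the VQ loss
sweep: lambda_vq
values: [0.10, 0.20, 0.25, 0.30, 0.35]
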