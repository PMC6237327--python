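df.prior 6.4092654122823944
s2.prior 0.050788885448544728
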