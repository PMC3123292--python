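# ligand profile: slightly deeper attraction at the small-molecule interface
rep 1.0
atr 1.2
elec 1.0
softness 1.0
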