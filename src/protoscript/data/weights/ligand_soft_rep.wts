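# soft ligand profile for early docking stages
rep 1.0
atr 1.2
elec 1.0
softness 0.5
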