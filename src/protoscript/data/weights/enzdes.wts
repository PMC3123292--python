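# enzyme-design surrogate: electrostatics emphasised
rep 1.0
atr 1.0
elec 1.5
softness 1.0
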