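# docking profile: reduced repulsive weight to tolerate near-clashes
rep 0.5
atr 1.0
elec 1.0
softness 1.0
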