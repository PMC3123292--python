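# soft-repulsive variant: repulsion softened to half stiffness
rep 1.0
atr 1.0
elec 1.0
softness 0.5
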