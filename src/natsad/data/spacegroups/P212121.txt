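# Hermann-Mauguin: P 21 21 21
# One symmetry operator per line (centering translations expanded)
x,y,z
-x+1/2,-y,z+1/2
x+1/2,-y+1/2,-z
-x,y+1/2,-z+1/2
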