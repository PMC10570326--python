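# Hermann-Mauguin: P 31 2 1
# One symmetry operator per line (centering translations expanded)
x,y,z
-y,x-y,z+1/3
-x+y,-x,z+2/3
y,x,-z
x-y,-y,-z+2/3
-x,-x+y,-z+1/3
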