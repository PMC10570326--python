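# Hermann-Mauguin: P 65
# One symmetry operator per line (centering translations expanded)
x,y,z
x-y,x,z+5/6
-y,x-y,z+2/3
-x,-y,z+1/2
-x+y,-x,z+1/3
y,-x+y,z+1/6
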