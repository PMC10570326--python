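# Hermann-Mauguin: R 3
# One symmetry operator per line (centering translations expanded)
x,y,z
-y,x-y,z
-x+y,-x,z
x+2/3,y+1/3,z+1/3
-y+2/3,x-y+1/3,z+1/3
-x+y+2/3,-x+1/3,z+1/3
x+1/3,y+2/3,z+2/3
-y+1/3,x-y+2/3,z+2/3
-x+y+1/3,-x+2/3,z+2/3
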