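raw_code,space,chirality,model_state
o1l,O,left,0
o1r,O,right,0
o2l,O,left,1
o2r,O,right,1
o3l,O,left,2
o3r,O,right,2
o4l,O,left,3
o4r,O,right,3
o5l,O,left,4
o5r,O,right,4
o6,O,none,5
d1l,D,left,6
d1r,D,right,6
d2l,D,left,7
d2r,D,right,7
d3l,D,left,8
d3r,D,right,8
d4l,D,left,9
d4r,D,right,9
t1l,T,left,10
t1r,T,right,10
t2l,T,left,11
t2r,T,right,11
t3l,T,left,12
t3r,T,right,12
t4,T,none,13
x1,X,none,
x2,X,none,
x3,X,none,
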