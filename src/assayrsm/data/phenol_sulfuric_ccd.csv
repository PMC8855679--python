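run_index,point_type,phenol_coded,h2so4_coded,water_coded,absorbance
1,center,0,0,0,0.292
2,factorial,-1,-1,-1,0.344
3,factorial,1,-1,-1,0.256
4,factorial,1,-1,1,0.044
5,axial,0,-1.682,0,0.043
6,center,0,0,0,0.31
7,center,0,0,0,0.292
8,axial,0,1.682,0,0.221
9,axial,-1.682,0,0,0.249
10,axial,0,0,-1.682,0.378
11,center,0,0,0,0.29
12,factorial,1,1,1,0.232
13,axial,0,0,1.682,0.069
14,factorial,-1,-1,1,0.048
15,factorial,1,1,-1,0.328
16,factorial,-1,1,-1,0.26
17,center,0,0,0,0.269
18,factorial,-1,1,1,0.224
19,axial,1.682,0,0,0.287
20,center,0,0,0,0.298
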