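id,dg_obs,dg_calc,residual,flag_a,flag_b,flag_c,flag_d,total
9,-33.3,-21.7,-11.6,0,0,1,0,1
10,-29.1,-22.6,-6.5,0,0,0,0,0
11,-22.2,-20.4,-1.8,0,0,0,0,0
12,-29.6,-23.2,-6.4,1,0,1,0,2
14,-32.0,-40.0,8.0,0,1,1,1,3
17,-30.0,-37.8,7.8,0,1,1,1,3
20,-28.1,-35.1,7.0,0,1,1,1,3
29,-26.4,-22.6,-3.9,0,0,0,0,0
31,-28.9,-25.6,-3.3,0,0,0,0,0
33,-29.8,-22.8,-7.0,0,0,0,0,0
34,-32.0,-26.7,-5.3,0,0,0,0,0
37,-34.1,-27.3,-6.8,0,0,0,0,0
39,-26.9,-24.9,-2.0,0,0,0,0,0
40,-28.2,-26.3,-1.9,0,0,0,0,0
41,-31.2,-25.1,-6.1,0,0,0,0,0
43,-25.8,-25.8,0.0,0,0,0,0,0
57,-26.1,-31.4,5.4,0,0,0,1,1
59,-25.5,-31.0,5.5,0,0,0,1,1
63,-20.4,-17.7,-2.8,0,0,0,0,0
66,-22.6,-25.5,2.8,0,0,0,0,0
69,-15.7,-21.7,6.0,0,0,0,0,0
71,-9.7,-15.3,5.6,1,0,0,0,1
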