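id,compound,dg_obs,dg_calc,residual
1,Mefenamic Acid,-29.7,-34.0,4.3
2,Tacrine,-32.2,-29.4,-2.8
4,Nifedipine,-31.9,-29.0,-2.9
6,Phenacetin,-27.9,-23.6,-4.3
7,alpha-naphthoflavon,-42.6,-41.3,-1.3
13,HET-0016,-36.1,-36.4,0.3
16,Niflumic acid,-30.2,-33.1,2.9
23,Mexiletine,-34.8,-27.0,-7.8
25,Propranolol,-32.9,-31.8,-1.1
27,Naphthalene,-19.8,-17.6,-2.3
28,1-Methylnaphthalene,-24.5,-22.3,-2.1
30,2-Methylnaphthalene,-24.2,-20.9,-3.3
32,2-Fluoronaphthalene,-26.5,-20.9,-5.6
35,"1,3-Dimethylnaphthalene",-31.0,-25.1,-5.9
36,"1,4-Dimethylnaphthalene",-33.0,-25.7,-7.4
38,"1,5-Dichloronaphthalene",-29.6,-26.9,-2.7
42,"2,6-Dimethylnaphthalene",-26.3,-24.4,-1.9
50,epsilon-Caprolactone,-9.7,-16.3,6.6
51,gamma-Valerolactone,-12.2,-15.8,3.6
52,gamma-Caprolactone,-13.2,-17.2,4.0
53,gamma-Heptalactone,-15.2,-20.2,5.0
54,gamma-Nonanoic-lactone,-21.9,-25.4,3.6
55,gamma-Decanolactone,-22.6,-25.9,3.3
56,gamma-Undecanolactone,-25.5,-29.9,4.4
58,delta-decanolactone,-22.6,-26.3,3.6
60,2-Coumarone,-22.3,-21.2,-1.1
61,2-Indanone,-25.3,-18.4,-6.8
62,"2,3-Dihydrobenzofuran",-18.5,-18.1,-0.4
64,2-Benzoxalinone,-21.4,-22.2,0.8
65,Biphenyl,-23.5,-23.0,-0.5
67,4-Chlorobiphenyl,-26.5,-26.6,0.1
68,Butylcyclohexane,-26.2,-28.4,2.2
70,gamma-Phenyl-gamma-butyrolactone,-16.9,-22.6,5.7
72,2-(p-tolyl)ethylamine,-15.2,-19.6,4.4
73,Cotinine,-14.7,-22.4,7.7
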