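id,compound,ic50_inhouse_uM,ic50_inhouse_err_uM,ic50_lit_uM,ic50_lit_err_uM,dg_inhouse,dg_inhouse_err,dg_lit,dg_lit_err,ddg
1,Mefenamic acid,19,7,13.98,,-28.9,1.0,-29.7,,-0.8
2,Tacrine,2.3,1.0,5.2,,-34.2,1.2,-32.1,,2.1
3,Carvedilol,5.0,0.2,5.91,,-32.2,0.1,-31.8,,0.4
4,Nifedipine,0.7,0.2,5.74,,-37.2,0.7,-31.9,,5.3
5,Ellipticine,0.007,0.002,0.11,0.01,-48.7,0.7,-41.8,0.2,6.9
6,Phenacetin,24,6,28.0,0.46,-28.3,0.6,-27.9,0.0,0.4
7,alpha-Naphthoflavone,0.030,0.026,0.08,0.02,-45.0,3.7,-42.6,0.6,2.4
8,Ticlopidine,12,7,6.1,0.45,-30.1,1.7,-31.8,0.2,-1.7
9,1-naphthol,2.0,0.7,3.2,0.8,-34.5,0.9,-33.3,0.6,1.2
10,2-naphthol,4.4,1.2,17,1.5,-32.6,0.7,-29.1,0.2,3.4
11,4-methoxy-benzaldehyde,410,32,270,85,-21.2,0.2,-22.2,0.8,-1.0
12,2-(p-tolyl)ethylamine,120,33,14,2.5,-24.3,0.7,-29.6,0.5,-5.3
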