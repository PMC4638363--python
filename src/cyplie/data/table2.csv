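id,compound,predicted,reported
1,Mefenamic acid,Competitive,Competitive
2,Tacrine,Competitive,Substrate
3,Carvedilol,Quasi-irreversible,Substrate
4,Nifedipine,Competitive,Competitive
6,Phenacetin,Competitive,Substrate
7,alpha-Naphthoflavone,Competitive,Competitive/uncompetitive
8,Ticlopidine,Mechanism-based,Competitive
14,Quercetin,Competitive,Competitive
17,Naringenin,Competitive,Substrate
19,Clopidogrel,Mechanism-based,Substrate
23,Mexiletine,Competitive,Competitive
24,Furafylline,Mechanism-based,Mechanism-based
25,Propranolol,Competitive,Substrate
26,Riluzole,Mechanism-based,Substrate
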