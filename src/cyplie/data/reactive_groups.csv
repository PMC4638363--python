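name,smarts,reactive_atoms,mechanism
terminal_alkene,[CX3]=[CX3H2],1,mechanism-based
terminal_alkyne,[CX2]#[CX2H1],1,mechanism-based
furan,o1cccc1,0;1;2;3;4,mechanism-based
thiophene,s1cccc1,0;1;2;3;4,mechanism-based
methylenedioxyphenyl,[CH2]1Oc2ccccc2O1,0,mechanism-based
aromatic_primary_amine,[NX3H2][c],0,mechanism-based
hydrazine,[NX3][NX3],0;1,mechanism-based
dihydropyridine,[NX3H1]1[CX3]=[CX3][CX4][CX3]=[CX3]1,0;3,mechanism-based
heteroaromatic_nitrogen,[nX2],0,quasi-irreversible
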