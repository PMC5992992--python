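condition,normal,mild,severe
wt + dhx37 MO,3,32,3
wt + dhx37 MO + control RNA,2,26,3
wt + dhx37 MO + GlyR a1,35,43,1
wt + dhx37 MO + GlyR a1 Q177K,14,47,2
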