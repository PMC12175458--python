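group,zone:MRSA,zone:Listeria monocytogenes,zone:Candida albicans,zone:Salmonella enterica,zone:E. coli,zone:Enterobacter sp.,zone:Pseudomonas sp.,zone:Klebsiella sp.,zone:Enterococcus sp.,zone:Staphylococcus aureus 2
6,23,22,20,22,26,18,NA,25,13,21
10,23,23,22,21,24,24,13,26,16,25
12,22,22,19,23,21,20,NA,26,15,23
35,30,27,17,27,26,23,NA,25,13,26
42,29,25,16,23,21,21,NA,24,15,25
43,32,28,24,27,27,23,NA,27,13,25
45,30,28,20,25,27,22,14,26,NA,27
48,31,35,20,25,28,15,NA,20,14,25
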