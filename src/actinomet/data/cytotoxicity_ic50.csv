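group,cell_line,ic50_mean,ic50_sd
6,HCT-116,NA,NA
6,MCF-7,30.91,1.84
6,HSF,48.93,3.95
10,HCT-116,NA,NA
10,MCF-7,48.36,3.42
10,HSF,88.16,10.23
12,HCT-116,NA,NA
12,MCF-7,31.17,0.73
12,HSF,56.51,1.39
35,HCT-116,NA,NA
35,MCF-7,47.61,1.84
35,HSF,NA,NA
42,HCT-116,NA,NA
42,MCF-7,29,1.04
42,HSF,64.43,6.86
43,HCT-116,NA,NA
43,MCF-7,24.62,0.93
43,HSF,40.74,5.31
45,HCT-116,NA,NA
45,MCF-7,23.78,1.45
45,HSF,38.15,1.18
48,HCT-116,NA,NA
48,MCF-7,55.50,8.91
48,HSF,67.37,2.33
5-FU,HCT-116,1.25,0.18
5-FU,MCF-7,0.011,0.01
5-FU,HSF,0.22,0.04
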