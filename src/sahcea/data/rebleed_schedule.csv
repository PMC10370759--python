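# source: fixture — synthetic stand-in generated by sahcea.fixtures; not data from the published study or its supplement
year,prob
1,0.58
2,0.4872
3,0.4092
4,0.3438
5,0.2888
6,0.2426
7,0.2038
8,0.1712
9,0.16
10,0.16
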