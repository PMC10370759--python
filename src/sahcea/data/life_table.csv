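# source: fixture — synthetic stand-in generated by sahcea.fixtures; not data from the published study or its supplement
age,qx
0,2.3e-05
1,2.5292153667900366e-05
2,2.7812740746116783e-05
3,3.0584526646793894e-05
4,3.3632545556987165e-05
5,3.6984326542173005e-05
6,4.067014218297591e-05
7,4.472328199074712e-05
8,4.9180353071426825e-05
9,5.408161075322275e-05
10,5.947132216426446e-05
11,6.539816604399068e-05
12,7.191567239928159e-05
13,7.908270597621787e-05
14,8.696399791408196e-05
15,9.563073038338816e-05
16,0.00010516117948826966
17,0.00011564142223978124
18,0.0001271661139853521
19,0.00013983934331596778
20,0.00015377557217242317
21,0.00016910066964148833
22,0.00018595304877901635
23,0.00020448491672754154
24,0.00022486364941916488
25,0.0002472733032797562
26,0.00027191627758786635
27,0.00029901514250242465
28,0.00032881464926958485
29,0.0003615839407644827
30,0.0003976189823330557
31,0.0004372452348887741
32,0.00048082059440713345
33,0.0005287386243668007
34,0.0005814321103321465
35,0.0006393769687814023
36,0.0007030965454841548
37,0.0007731663422502239
38,0.0008502192147409176
39,0.0009349510882882119
40,0.0010281272433459187
41,0.0011305892273417294
42,0.0012432624553565118
43,0.001367164568278609
44,0.0015034146239222277
45,0.0016532432041221586
46,0.0018180035290899824
47,0.0019991836794143046
48,0.0021984200360915256
49,0.002417512059974692
50,0.0026584385441253164
51,0.0029233754858559485
52,0.003214715739880069
53,0.0035350906300723787
54,0.003887393715032405
55,0.004274806922096941
56,0.0047008292858382655
57,0.005169308550608162
58,0.005684475922555345
59,0.006250984284989112
60,0.006873950222242387
61,0.007559000231584882
62,0.008312321540562577
63,0.009140717988735093
64,0.010051671478523004
65,0.011053409550176306
66,0.012154979691186816
67,0.013366331051291524
68,0.014698404301099713
69,0.016163230445927896
70,0.01777403948730845
71,0.01954537991357975
72,0.02149325009877183
73,0.023635242796554445
74,0.02599070403428653
75,0.0285809078422649
76,0.031429248396289675
77,0.034561451308937834
78,0.03800580597788312
79,0.04179342108978373
80,0.0459585055873947
81,0.050538677637541086
82,0.0555753043904856
83,0.06111387559932606
84,0.06720441447387403
85,0.07390192947976032
86,0.0812669111633233
87,0.08936587848949486
88,0.09827197962709622
89,0.10806565260770842
90,0.11883535182504787
91,0.13067834693643965
92,0.143701601381897
93,0.15802273845540457
94,0.1737711036537616
95,0.19108893289789494
96,0.210132637177768
97,0.2310742152235329
98,0.25410280696187304
99,0.27942640178802214
100,0.30727371708222306
101,0.3378962639369797
102,0.37157061875232616
103,0.4086009212156809
104,0.44932162122750696
105,0.49410049958244423
106,0.5433419896880665
107,0.5974908303223184
108,0.6570360824205845
109,0.7225155461711602
110,1.0
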