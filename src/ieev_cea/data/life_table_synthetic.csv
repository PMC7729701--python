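age,q
0,5.118212967758495e-05
1,5.5722731576723916e-05
2,6.066613891453354e-05
3,6.604808306376331e-05
4,7.190746457519381e-05
5,7.828663418807391e-05
6,8.523169874441461e-05
7,9.279285420948913e-05
8,0.00010102474819861929
9,0.00010998687462016044
10,0.00011974400327563473
11,0.00013036664750765148
12,0.00014193157326025663
13,0.0001545223532101181
14,0.00016822996995125017
15,0.00018315347256514514
16,0.00019940069128865368
17,0.00021708901540518077
18,0.0002363462399370686
19,0.00025731148720098407
20,0.00028013620982325627
21,0.0003049852823864274
22,0.00033203818950400255
23,0.00036149031880083893
24,0.00039355436801513655
25,0.00042846187623590826
26,0.00046646489016111126
27,0.0005078377772010922
28,0.0005528791982746251
29,0.0006019142542490474
30,0.0006552968211755994
31,0.0007134120907680286
32,0.000776679333974406
33,0.0008455549070115476
34,0.0009205355208709021
35,0.0010021617970750185
36,0.0010910221343752857
37,0.001187756913143878
38,0.0012930630664287346
39,0.0014076990490303753
40,0.0015324902385258632
41,0.0016683348049174596
42,0.001816210088534831
43,0.0019771795289798
44,0.0021524001912710533
45,0.002343130938940119
46,0.0025507413076527596
47,0.0027767211369748024
48,0.0030226910221874403
49,0.0032904136525617744
50,0.0035818061072346863
51,0.0038989531847629655
52,0.0042441218475609555
53,0.004619776867708869
54,0.005028597766027931
55,0.0054734971417927936
56,0.0059576404959322815
57,0.006484467655961668
58,0.00705771591610127
59,0.007681445010908616
60,0.008360064045143889
61,0.009098360506277103
62,0.009901531488786586
63,0.010775217260891035
64,0.01172553730423409
65,0.012759128954853205
66,0.013883188769005184
67,0.015105516729440494
68,0.016434563395798518
69,0.017879480086035016
70,0.019450172153184453
71,0.021157355392073307
72,0.02301261557244849
73,0.025028471046716017
74,0.027218438320220417
75,0.029597100397570575
76,0.032180177627435747
77,0.03498460065771669
78,0.038028584979834634
79,0.041331706381577016
80,0.04491497643855458
81,0.04880091695059374
82,0.05301363196672171
83,0.05757887573591847
84,0.06252411456551021
85,0.06787858015994475
86,0.07367331154497048
87,0.0799411821517475
88,0.08671690803898635
89,0.09403703256729767
90,0.10193988210937366
91,0.11046548658662525
92,0.11965545777628794
93,0.12955281744774927
94,0.14020176648591165
95,0.15164738527595711
96,0.1639352548038756
97,0.17711098723217167
98,0.19121965422069898
99,0.2063051010811282
100,0.2224091351078351
101,0.23957057727366038
102,0.25782416810102804
103,0.2771993211316719
104,0.2977187212620487
105,0.3193967705458781
106,0.34223789115528713
107,0.3662347042883083
108,0.39136611511798514
109,0.41759534751462835
110,1.0
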