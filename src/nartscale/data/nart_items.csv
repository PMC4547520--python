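difficulty_rank,label,test_order,pct_correct,mini,h_i
1,ACHE,2,99.3,0,
2,AISLE,4,99.1,1,0.570
3,DEBT,10,99.0,1,0.592
4,CHORD,1,99.0,0,
5,PSALM,6,98.5,1,0.409
6,HEIR,18,98.0,1,0.508
7,DEPOT,3,97.4,1,0.391
8,NAUSEA,9,97.4,1,0.483
9,BOUQUET,5,96.9,1,0.455
10,NAIVE,14,93.0,1,0.502
11,PROCREATE,23,93.0,0,
12,DENY,8,91.6,0,
13,GOUGE,25,90.6,0,
14,PLACEBO,35,89.9,0,
15,ASSIGNATE,20,89.8,0,
16,COURTEOUS,11,89.4,0,
17,SUBTLE,22,89.1,0,
18,RAREFY,12,88.6,0,
19,THYME,17,86.7,1,0.484
20,EQUIVOCAL,13,85.8,0,
21,SIMILE,27,85.7,0,
22,CAPON,7,85.3,0,
23,SUPERFLUOUS,26,84.7,0,
24,HIATUS,21,84.7,0,
25,GIST,24,83.1,1,0.534
26,ZEALOT,32,80.6,0,
27,BANAL,28,79.4,0,
28,CATACOMB,15,78.4,0,
29,GAOLED,16,76.8,1,0.462
30,FACADE,31,75.1,0,
31,CELLIST,30,72.9,1,0.526
32,TOPIARY,42,72.6,0,
33,QUADRUPED,29,69.5,1,0.519
34,ABSTEMIOUS,36,67.6,1,0.541
35,GAUCHE,41,63.2,1,0.502
36,AVER,40,58.4,1,0.476
37,DETENTE,37,55.0,1,0.550
38,IDYLL,38,47.5,1,0.523
39,RADIX,19,44.1,0,
40,AEON,34,42.4,0,
41,PUERPERAL,39,40.7,0,
42,BEATIFY,44,37.3,1,0.561
43,LEVIATHAN,43,35.7,1,0.622
44,PRELATE,45,31.7,0,
45,SYNCOPE,48,28.8,0,
46,DEMESNE,47,22.0,1,0.701
47,CAMPANILE,50,17.4,0,
48,SIDEREAL,46,17.2,1,0.606
49,LABILE,49,14.1,1,0.581
50,DRACHM,33,13.8,0,
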