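index,name,ic50_uM,log_ic50,mw,hba,hbd,nrot,naro,tpsa,logp
1,Viscosol,13.5,1.13,388.246,7,2,6,17,98.36,4.406
2,Penduletin,57.9,1.762,328.191,7,2,4,17,98.36,2.897
3,"5,6-Dihydroxy-3,4',7-trimethoxyflavone",32.2,1.507,328.191,7,2,4,17,98.36,2.897
4,Kaempferol 3-O-rutinoside,20.5,1.311,564.282,15,9,6,17,249.2,-1.393
5,Isorhamnetin3-O-robinobioside,42.9,1.632,592.292,16,9,7,17,258.43,-1.384
6,Erybraedin A,2.4,0.38,364.271,4,2,4,12,58.92,5.725
7,Luteolin,6.70,0.826,276.159,6,4,1,17,111.13,2.282
8,2'-Methoxykurarinone,5.26,0.72,420.291,6,2,8,12,85.22,5.913
9,Mulberrofuran D,4.3,0.633,412.315,4,3,8,16,73.83,7.961
10,Mulberrofuran W,2.7,0.431,412.315,4,3,9,16,73.83,8.178
11,Catechin,2.245,0.351,276.159,6,5,1,12,110.38,1.546
12,Epicatechin,0.832,-0.079,276.159,6,5,1,12,110.38,1.546
13,Trans-resveratrol,16.1,1.206,216.151,3,3,2,12,60.69,2.974
14,Apigenin,24.76,1.393,260.16,5,3,1,17,90.9,2.577
15,Isovitexin,17.76,1.249,412.221,10,7,3,17,181.05,0.092
16,Vitexin,7.62,0.881,412.221,10,7,3,17,181.05,0.092
17,Isoorientin,24.54,1.389,428.22,11,8,3,17,201.28,-0.203
18,Orientin,57.11,1.756,428.22,11,8,3,17,201.28,-0.203
19,abyssinin II/5'-Prenylhomoeriodictyol,40.5,1.607,348.225,6,3,4,12,96.22,4.027
20,Parvisoflavone B,42.6,1.629,336.214,6,3,1,17,100.13,3.761
21,Neorautenol,7.6,0.88,304.216,4,1,0,12,47.92,4.186
22,Erybreadin D,4.2,0.623,364.271,4,1,2,12,47.92,5.695
23,Erybreadin B,7.8,0.892,364.271,4,1,2,12,47.92,5.695
24,Folitenol,6.4,0.806,364.271,4,1,2,12,47.92,5.695
25,Erysubin E,8.8,0.944,380.27,5,2,2,12,68.15,4.799
26,Erybreadin C,7.3,0.863,364.271,4,2,4,12,58.92,5.725
27,Licoagrone,6.0,0.778,700.485,10,5,10,24,170.82,8.71
28,Erythraddison III,4.6,0.662,332.226,5,2,4,12,75.99,3.974
29,Erysubin F,7.8,0.892,364.271,4,2,5,17,70.67,5.889
30,2'-Methoxykurarinone,5.26,0.72,420.291,6,2,8,12,85.22,5.913
31,Mimulone/ Bonannione A,1.9,0.278,380.27,5,3,6,12,86.99,5.745
32,3'-O-Methyldiplacone,3.9,0.591,408.28,6,3,7,12,96.22,5.754
33,"6-geranyl-3',5,5',7-Tetrahydroxy-4'-methoxyflavanone",5.9,0.77,424.279,7,4,7,12,116.45,5.459
34,4'-O-methyldiplacone,7.8,0.892,408.28,6,3,7,12,96.22,5.754
35,3'-O-methyldiplacol,4.9,0.69,424.279,7,4,7,12,116.45,4.725
36,4'-O-methyldiplacol,8.2,0.913,424.279,7,4,7,12,116.45,4.725
37,"6-geranyl-3,3',5,5',7-Pentahydroxy-4'-methoxyflavane",6.6,0.819,424.279,7,5,7,12,119.61,4.79
38,Laxichalcone,20.7,1.315,380.27,5,2,3,12,75.99,5.362
39,Macarangin,22.7,1.356,396.269,6,4,6,17,111.13,5.518
40,Bonanniol A,15.2,1.181,396.269,6,4,6,12,107.22,4.716
41,"7,4'-Dimethylkaempferol/3,5-Dihydroxy-7-methoxy-2-(4-methoxyphenyl)-4H-chromen-4-one",16.92,1.228,300.181,6,2,3,17,89.13,2.888
42,"2S-5,6,7,3',4'-Pentamethoxyflavanone",6.88,0.837,352.213,7,0,6,12,72.45,3.436
43,"3'-Hydroxy-3,5,7,4'-tetramethoxyflavone",22.25,1.347,340.202,7,1,5,17,87.36,3.2
44,"3,5-Dihydroxy-7,3',4'-trimethoxyflavone",52.64,1.721,328.191,7,2,4,17,98.36,2.897
45,Lutein,13.691,1.136,512.438,2,2,10,1,40.46,10.403
46,Silydianin,17.38,1.24,460.265,10,5,3,12,162.98,0.99
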