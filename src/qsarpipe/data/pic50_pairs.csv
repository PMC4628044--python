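compound_id,cell_line,exp_pic50,loo_pred_pic50,citation
1,HuCCA-1,-0.937,-1.004,Table 4
1,HepG2,-0.958,-1.571,Table 4
1,A549,-1.538,-1.345,Table 4
2,HepG2,-1.76,-1.64,Table 4
3,HepG2,-1.45,-1.543,Table 4
3,MOLT-3,-1.871,-1.797,Table 4
4,HepG2,-1.912,-1.514,Table 4
5,HuCCA-1,-1.944,-1.79,Table 4
5,HepG2,-2.002,-1.835,Table 4
5,MOLT-3,-1.505,-1.588,Table 4
6,MOLT-3,-1.788,-1.548,Table 4
7,HepG2,-1.619,-1.624,Table 4
7,MOLT-3,-1.535,-1.513,Table 4
8,HepG2,-1.694,-1.711,Table 4
8,MOLT-3,-0.945,-0.833,Table 4
9,HepG2,-1.76,-1.426,Table 4
9,A549,-1.899,-1.76,Table 4
9,MOLT-3,-0.965,-1.306,Table 4
10,HepG2,-1.538,-1.524,Table 4
10,A549,-1.592,-1.79,Table 4
10,MOLT-3,-1.014,-1.074,Table 4
11,HuCCA-1,-1.207,-1.42,Table 4
11,HepG2,-1.095,-1.739,Table 4
11,A549,-1.292,-1.544,Table 4
11,MOLT-3,-1.949,-1.785,Table 4
12,MOLT-3,-1.027,-1.497,Table 4
13,HepG2,-1.378,-0.589,Table 4
13,A549,-1.26,-1.231,Table 4
13,MOLT-3,-1.785,-1.775,Table 4
14,A549,-1.448,-1.54,Table 4
14,MOLT-3,-1.241,-1.319,Table 4
15,MOLT-3,-1.004,-1.238,Table 4
16,HuCCA-1,-1.711,-1.454,Table 4
17,HepG2,-0.813,-1.241,Table 4
18,HepG2,-1.782,-1.112,Table 4
19,A549,-1.822,-1.498,Table 4
20,HuCCA-1,-1.479,-1.665,Table 4
20,HepG2,-1.281,-1.09,Table 4
20,A549,-1.173,-1.415,Table 4
20,MOLT-3,-1.34,-1.216,Table 4
21,HuCCA-1,0.201,-0.306,Table 4
21,HepG2,-1.092,-0.858,Table 4
21,A549,0.244,-0.857,Table 4
21,MOLT-3,-1.27,-1.423,Table 4
22,HepG2,-0.722,-1.259,Table 4
22,A549,-1.771,-1.635,Table 4
23,HuCCA-1,-1.394,-1.051,Table 4
23,A549,-1.403,-1.252,Table 4
23,MOLT-3,-1.907,-1.64,Table 4
24,HuCCA-1,-1.857,-2.031,Table 4
24,HepG2,-1.502,-1.431,Table 4
24,A549,-1.613,-1.524,Table 4
25,HepG2,-0.41,-0.589,Table 4
26,HepG2,-0.1,-0.859,Table 4
26,MOLT-3,-1.561,-1.604,Table 4
27,HuCCA-1,-1.599,-1.652,Table 4
27,HepG2,-0.17,-0.456,Table 4
27,A549,-1.435,-1.449,Table 4
28,HepG2,0.252,-0.449,Table 4
29,HuCCA-1,-0.68,-0.173,Table 4
29,HepG2,-0.528,-0.59,Table 4
29,A549,-0.926,0.176,Table 4
29,MOLT-3,-1.07,-0.609,Table 4
30,HuCCA-1,-1.493,-1.57,Table 4
30,HepG2,-1.097,-0.866,Table 4
30,A549,-1.503,-1.573,Table 4
30,MOLT-3,-1.533,-1.412,Table 4
31,HuCCA-1,-1.882,-1.802,Table 4
31,HepG2,-1.617,-0.653,Table 4
31,A549,-1.504,-1.664,Table 4
31,MOLT-3,-0.765,-0.843,Table 4
32,HuCCA-1,-1.602,-1.652,Table 4
32,MOLT-3,-0.74,-0.749,Table 4
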