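compound_id,cell_line,ic50_uM,inactive,citation
1,HuCCA-1,8.65,false,Table 1
1,HepG2,9.07,false,Table 1
1,A549,34.54,false,Table 1
1,MOLT-3,,true,Table 1
2,HuCCA-1,,true,Table 1
2,HepG2,57.54,false,Table 1
2,A549,,true,Table 1
2,MOLT-3,,true,Table 1
3,HuCCA-1,,true,Table 1
3,HepG2,28.21,false,Table 1
3,A549,,true,Table 1
3,MOLT-3,74.23,false,Table 1
4,HuCCA-1,,true,Table 1
4,HepG2,81.75,false,Table 1
4,A549,,true,Table 1
4,MOLT-3,,true,Table 1
5,HuCCA-1,87.89,false,Table 1
5,HepG2,100.54,false,Table 1
5,A549,,true,Table 1
5,MOLT-3,32.02,false,Table 1
6,HuCCA-1,,true,Table 1
6,HepG2,,true,Table 1
6,A549,,true,Table 1
6,MOLT-3,61.42,false,Table 1
7,HuCCA-1,,true,Table 1
7,HepG2,41.62,false,Table 1
7,A549,,true,Table 1
7,MOLT-3,34.24,false,Table 1
8,HuCCA-1,,true,Table 1
8,HepG2,49.4,false,Table 1
8,A549,,true,Table 1
8,MOLT-3,8.81,false,Table 1
9,HuCCA-1,,true,Table 1
9,HepG2,57.52,false,Table 1
9,A549,79.18,false,Table 1
9,MOLT-3,9.22,false,Table 1
10,HuCCA-1,,true,Table 1
10,HepG2,34.51,false,Table 1
10,A549,39.04,false,Table 1
10,MOLT-3,10.33,false,Table 1
11,HuCCA-1,16.12,false,Table 1
11,HepG2,12.44,false,Table 1
11,A549,19.6,false,Table 1
11,MOLT-3,88.97,false,Table 1
12,HuCCA-1,,true,Table 1
12,HepG2,,true,Table 1
12,A549,,true,Table 1
12,MOLT-3,10.65,false,Table 1
13,HuCCA-1,,true,Table 1
13,HepG2,23.89,false,Table 1
13,A549,18.19,false,Table 1
13,MOLT-3,60.99,false,Table 1
14,HuCCA-1,,true,Table 1
14,HepG2,,true,Table 1
14,A549,28.03,false,Table 1
14,MOLT-3,17.43,false,Table 1
15,HuCCA-1,,true,Table 1
15,HepG2,,true,Table 1
15,A549,,true,Table 1
15,MOLT-3,10.1,false,Table 1
16,HuCCA-1,51.35,false,Table 1
16,HepG2,,true,Table 1
16,A549,,true,Table 1
16,MOLT-3,,true,Table 1
17,HuCCA-1,,true,Table 1
17,HepG2,6.5,false,Table 1
17,A549,,true,Table 1
17,MOLT-3,,true,Table 1
18,HuCCA-1,,true,Table 1
18,HepG2,60.48,false,Table 1
18,A549,,true,Table 1
18,MOLT-3,,true,Table 1
19,HuCCA-1,,true,Table 1
19,HepG2,,true,Table 1
19,A549,66.3,false,Table 1
19,MOLT-3,,true,Table 1
20,HuCCA-1,30.16,false,Table 1
20,HepG2,19.12,false,Table 1
20,A549,14.9,false,Table 1
20,MOLT-3,21.86,false,Table 1
21,HuCCA-1,0.63,false,Table 1
21,HepG2,12.36,false,Table 1
21,A549,0.57,false,Table 1
21,MOLT-3,18.63,false,Table 1
22,HuCCA-1,,true,Table 1
22,HepG2,5.27,false,Table 1
22,A549,59.07,false,Table 1
22,MOLT-3,,true,Table 1
23,HuCCA-1,24.8,false,Table 1
23,HepG2,,true,Table 1
23,A549,25.29,false,Table 1
23,MOLT-3,80.78,false,Table 1
24,HuCCA-1,72.0,false,Table 1
24,HepG2,31.79,false,Table 1
24,A549,41.04,false,Table 1
24,MOLT-3,,true,Table 1
25,HuCCA-1,,true,Table 1
25,HepG2,2.57,false,Table 1
25,A549,,true,Table 1
25,MOLT-3,,true,Table 1
26,HuCCA-1,,true,Table 1
26,HepG2,1.26,false,Table 1
26,A549,,true,Table 1
26,MOLT-3,36.35,false,Table 1
27,HuCCA-1,39.71,false,Table 1
27,HepG2,1.48,false,Table 1
27,A549,27.21,false,Table 1
27,MOLT-3,,true,Table 1
28,HuCCA-1,,true,Table 1
28,HepG2,0.56,false,Table 1
28,A549,,true,Table 1
28,MOLT-3,,true,Table 1
29,HuCCA-1,4.79,false,Table 1
29,HepG2,3.37,false,Table 1
29,A549,8.43,false,Table 1
29,MOLT-3,11.74,false,Table 1
30,HuCCA-1,31.09,false,Table 1
30,HepG2,12.49,false,Table 1
30,A549,31.84,false,Table 1
30,MOLT-3,34.12,false,Table 1
31,HuCCA-1,76.15,false,Table 1
31,HepG2,41.36,false,Table 1
31,A549,31.91,false,Table 1
31,MOLT-3,5.82,false,Table 1
32,HuCCA-1,39.98,false,Table 1
32,HepG2,,true,Table 1
32,A549,,true,Table 1
32,MOLT-3,5.5,false,Table 1
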