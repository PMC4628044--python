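compound_id,descriptor,value,citation
7D,R5e+,0.057,"Results, HuCCA-1 section"
8N,R5e+,0.022,"Results, HuCCA-1 section"
21,R5e+,0.023,"Results, HuCCA-1 section"
29,R5e+,0.028,"Results, HuCCA-1 section"
21,MATS7m,-0.02,"Results, HepG2 section"
29,MATS7m,0.04,"Results, HepG2 section"
28,MATS7m,0.064,"Results, HepG2 section"
28,RDF105m,14.609,"Results, HepG2 section"
1P,RDF105m,18.976,"Results, HepG2 section"
19,MATS8v,0.164,"Results, A549 section"
20,MATS8v,0.249,"Results, A549 section"
21,MATS8v,0.348,"Results, A549 section"
8G,MATS8v,0.15,"Results, A549 section"
8B,MATS8v,0.146,"Results, A549 section"
9,Lop,0.74,"Results, MOLT-3 section"
10,Lop,0.74,"Results, MOLT-3 section"
31,Lop,0.876,"Results, MOLT-3 section"
32,Lop,0.876,"Results, MOLT-3 section"
8Q,Lop,0.983,"Results, MOLT-3 section"
8G,Lop,0.983,"Results, MOLT-3 section"
31,R7m,0.377,"Results, MOLT-3 section"
32,R7m,0.385,"Results, MOLT-3 section"
8D,R7m,0.365,"Results, MOLT-3 section"
8M,R7m,0.397,"Results, MOLT-3 section"
8G,R7m,0.519,"Results, MOLT-3 section"
8Q,R7m,0.537,"Results, MOLT-3 section"
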