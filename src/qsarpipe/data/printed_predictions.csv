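compound_id,cell_line,pic50,citation
7D,HuCCA-1,-3.915,"Results, HuCCA-1 section"
8N,HuCCA-1,0.054,"Results, HuCCA-1 section"
8A,HuCCA-1,-0.618,"Results, HuCCA-1 section"
8J,HuCCA-1,-1.038,"Results, HuCCA-1 section"
8B,HuCCA-1,-0.786,"Results, HuCCA-1 section"
8K,HuCCA-1,-1.122,"Results, HuCCA-1 section"
8M,HuCCA-1,-0.618,"Results, HuCCA-1 section"
8D,HuCCA-1,-2.466,"Results, HuCCA-1 section"
8R,HuCCA-1,-0.282,"Results, HuCCA-1 section"
8E,HuCCA-1,-0.114,"Results, HuCCA-1 section"
8F,HuCCA-1,-0.786,"Results, HuCCA-1 section"
8H,HuCCA-1,-0.702,"Results, HuCCA-1 section"
1P,HepG2,-0.151,"Results, HepG2 section"
7F,HepG2,-0.163,"Results, HepG2 section"
7P,HepG2,-1.177,"Results, HepG2 section"
8L,A549,-0.779,"Results, A549 section"
8Q,A549,-0.778,"Results, A549 section"
8Q,MOLT-3,0.947,"Results, MOLT-3 section"
8L,MOLT-3,0.11,"Results, MOLT-3 section"
8M,MOLT-3,-0.485,"Results, MOLT-3 section"
8D,MOLT-3,-0.818,"Results, MOLT-3 section"
8H,MOLT-3,-0.333,"Results, MOLT-3 section"
8R,MOLT-3,-0.645,"Results, MOLT-3 section"
7H,MOLT-3,-1.865,"Results, MOLT-3 section"
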