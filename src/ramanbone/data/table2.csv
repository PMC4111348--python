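sample_id,burial_no,phase,pct_n,pct_c,cn_atomic,pct_collagen,raman_ratio
1,560,Neolithic,0.11,2.11,-,1.88,-
4,80,Neolithic,-,3.43,-,0.12,0.189
6,146,Bronze,-,6.76,-,0.27,0.150
7,189,Bronze,2.74,9.28,-,6.00,-
10,532,Bronze,-,3.44,-,0.60,0.150
11,550,Bronze,-,1.04,-,1.75,0.247
31,479,Iron,-,-,-,0.16,0.208
32,516,Iron,-,3.72,-,0.40,0.295
37,329,Iron,-,1.85,-,0.26,0.147
39,481,Iron,-,1.27,-,0.79,0.145
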