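sample_id,burial_no,phase,pct_n,pct_c,cn_atomic,pct_collagen,raman_ratio
2,573,Neolithic,5.47,21.67,4.6,0.35,0.268
3,254,Neolithic,3.03,16.71,6.4,0.14,0.060
5,563,Neolithic,2.21,6.65,3.5,1.00,0.091
8,538,Bronze,11.37,34.19,3.5,1.19,0.213
9,536,Bronze,6.09,20.34,3.9,0.66,0.311
12,274,Bronze,1.88,7.58,4.7,0.39,0.294
13,130,Bronze,2.86,12.27,5.0,0.28,0.129
14,84,Bronze,5.00,20.51,4.8,0.64,0.204
15,163,Bronze,1.23,10.18,9.7,0.24,0.167
16,425,Bronze,7.26,23.32,3.7,0.30,0.236
17,526,Bronze,3.39,16.78,5.8,0.17,0.154
18,548,Bronze,7.84,25.33,3.8,0.61,0.199
19,559,Bronze,5.87,21.52,4.3,0.26,0.061
20,458,Bronze,10.98,33.50,3.6,0.45,0.240
21,168,Bronze,6.15,22.76,4.3,0.27,0.098
22,141,Bronze,2.94,9.45,3.8,1.30,0.228
23,527,Bronze,6.12,25.34,4.8,0.20,0.154
24,94,Bronze,12.40,35.84,3.4,2.23,0.424
25,280,Bronze,2.72,10.88,4.7,0.31,0.103
26,74,Bronze,0.86,3.82,5.2,0.67,0.087
28,519,Bronze,13.26,37.60,3.3,1.87,0.292
29,139,Bronze,11.25,31.51,3.3,1.49,0.216
30,515,Iron,11.54,34.41,3.5,0.82,0.252
33,584,Iron,14.35,40.77,3.3,2.99,0.597
34,541,Iron,6.29,18.33,3.4,1.47,0.314
35,488,Iron,0.95,3.73,4.6,0.77,0.142
36,484,Iron,7.50,25.89,4.0,0.37,0.244
38,496,Iron,0.51,2.20,5.0,0.60,0.120
40,493,Iron,2.12,6.65,3.7,0.79,0.155
41,511,Iron,12.99,36.50,3.3,3.90,0.393
42,528,Iron,10.56,32.77,3.6,0.79,0.361
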