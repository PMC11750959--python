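record,gene_id,chrom,diff_exp,diff_meth,context
1,Vitvi02g01812,chr00,1.35,-0.49,CHG
2,Vitvi04g01539,chr04,2.75,-0.28,CHG
3,Vitvi04g00498,chr04,1.01,-0.27,CG
4,Vitvi04g00159,chr04,1.44,-0.25,CHG
5,Vitvi03g00483,chr03,-2.86,0.13,CHH
6,Vitvi03g00483,chr03,-2.86,0.13,CHH
7,Vitvi04g01733,chr04,-1.39,0.13,CHH
8,Vitvi17g00607,chr17,-1.16,0.13,CHH
9,Vitvi08g00969,chr08,-2.41,0.14,CHH
10,Vitvi18g00262,chr18,-1.90,0.14,CHH
11,Vitvi05g02123,chr05,-2.50,0.14,CHH
12,Vitvi02g01690,chr00,-2.96,0.15,CHH
13,Vitvi03g00755,chr03,-3.27,0.18,CHH
14,Vitvi18g00430,chr18,-2.98,0.19,CHH
15,Vitvi07g00683,chr07,-1.00,0.23,CHH
16,Vitvi17g00926,chr17,-1.86,0.25,CHH
17,Vitvi18g02335,chr18,-1.18,0.28,CG
18,Vitvi06g00226,chr06,-1.17,-0.41,CG
19,Vitvi18g02508,chr18,-3.37,-0.31,CG
20,Vitvi18g00482,chr18,3.12,0.14,CHH
21,Vitvi02g00805,chr02,1.03,0.15,CHH
22,Vitvi16g00350,chr16,2.80,0.16,CHH
23,Vitvi10g00558,chr10,1.53,0.18,CHH
24,Vitvi14g00093,chr14,1.07,0.19,CHH
25,Vitvi03g00601,chr03,2.71,0.20,CHH
26,Vitvi11g01472,chr11,1.05,0.24,CHH
27,Vitvi14g00118,chr14,1.43,0.24,CHH
28,Vitvi10g00924,chr10,1.41,0.25,CHG
29,Vitvi02g01406,chr02,1.25,0.26,CHH
30,Vitvi16g01804,chr16,1.18,0.27,CHG
31,Vitvi08g00716,chr08,1.12,0.29,CG
32,Vitvi10g02090,chr00,3.10,0.31,CHH
33,Vitvi14g01368,chr14,1.07,0.34,CHG
34,Vitvi02g01753,chr00,2.37,0.37,CHG
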