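label,name,sigma_S_per_m
0,Air,0.00
1,Adrenal,0.20
2,Bile,1.40
3,Bladder,0.20
4,Blood,0.70
5,Bone (cancellous),0.07
6,Bone (cortical),0.02
7,Cartilage,0.15
8,Cerebellum,0.04
9,Cerebrospinal fluid,2.00
10,Colon,0.01
11,Content of the large intestine,0.20
12,Content of the small intestine,0.20
13,Content of the stomach,0.20
14,Cornea,0.40
15,Corpus spongiosum,0.20
16,Diaphragma sellae,0.20
17,Duodenum,0.50
18,Esophagus,0.50
19,Fat,0.04
20,Gall bladder,0.90
21,Glandula pinealis,0.02
22,Glandula salivaria,0.20
23,Glandula pituitaria,0.02
24,Gray matter,0.02
25,Heart,0.05
26,Hypothalamus,0.02
27,Internal air,0.00
28,Kidneys,0.05
29,Lens,0.30
30,Ligaments,0.25
31,Liver,0.02
32,Lung,0.20
33,Muscle,0.20
34,Nerve,0.01
35,Pancreas,0.50
36,Seminal capsule,0.20
37,Skin,0.10
38,Small intestine,0.50
39,Spleen,0.03
40,Stomach,0.50
41,Tendon,0.25
42,Testicle,0.20
43,Testis prostate,0.40
44,Thalamus,0.02
45,Thyroid thymus,0.50
46,Tongue,0.25
47,Tooth,0.02
48,Trachea,0.30
49,Urine,0.70
50,Vitreous humor,1.50
51,White matter,0.02
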