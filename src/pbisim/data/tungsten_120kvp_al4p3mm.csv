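# 120-kVp tungsten spectrum, 4.3 mm Al external filtration
# approximation: Kramers continuum + 3 mm Al-equivalent inherent
# filtration + W K lines; fluence-weighted mean energy 59.76 keV
# energy_keV relative_fluence
15.0 4.54001e-07
16.0 4.73454e-06
17.0 3.41244e-05
18.0 0.000179985
19.0 0.000729096
20.0 0.00236296
21.0 0.00455663
22.0 0.00816541
23.0 0.0137035
24.0 0.0216882
25.0 0.0325726
26.0 0.0466808
27.0 0.0641565
28.0 0.0849364
29.0 0.10875
30.0 0.135142
31.0 0.149836
32.0 0.164668
33.0 0.17948
34.0 0.194122
35.0 0.208451
36.0 0.222335
37.0 0.235658
38.0 0.248315
39.0 0.26022
40.0 0.2713
41.0 0.274128
42.0 0.276545
43.0 0.278555
44.0 0.280163
45.0 0.281376
46.0 0.282203
47.0 0.282653
48.0 0.282737
49.0 0.282467
50.0 0.281855
51.0 0.277919
52.0 0.273932
53.0 0.269898
54.0 0.265818
55.0 0.261695
56.0 0.257532
57.0 0.253331
58.0 0.66786
59.0 1
60.0 0.240528
61.0 0.234669
62.0 0.228918
63.0 0.223268
64.0 0.217717
65.0 0.212261
66.0 0.206895
67.0 0.47221
68.0 0.196421
69.0 0.247476
70.0 0.186271
71.0 0.181311
72.0 0.176423
73.0 0.171606
74.0 0.166857
75.0 0.162175
76.0 0.157557
77.0 0.153001
78.0 0.148506
79.0 0.144069
80.0 0.13969
81.0 0.134968
82.0 0.130335
83.0 0.12579
84.0 0.121329
85.0 0.116949
86.0 0.112647
87.0 0.108422
88.0 0.10427
89.0 0.10019
90.0 0.0961783
91.0 0.0922341
92.0 0.0883547
93.0 0.0845384
94.0 0.0807833
95.0 0.0770875
96.0 0.0734495
97.0 0.0698674
98.0 0.0663399
99.0 0.0628653
100.0 0.0594422
101.0 0.0559906
102.0 0.0525982
103.0 0.0492632
104.0 0.0459841
105.0 0.0427593
106.0 0.0395873
107.0 0.0364666
108.0 0.0333959
109.0 0.0303738
110.0 0.027399
111.0 0.0244703
112.0 0.0215865
113.0 0.0187463
114.0 0.0159488
115.0 0.0131928
116.0 0.0104772
117.0 0.00780111
118.0 0.0051635
119.0 0.00256343
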