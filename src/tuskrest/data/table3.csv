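rd,date,lat_s_ddmm_m1,lon_e_ddmm_m1,lat_s_ddmm_m2,lon_e_ddmm_m2
1,2014-04-14,18.05649,25.03646,18.00428,25.01540
2,2014-04-15,18.06846,25.03664,18.04721,25.04005
3,2014-04-16,18.05369,25.03899,18.05442,25.03827
4,2014-04-17,,,,
5,2014-04-18,17.52314,24.54497,17.52053,24.55184
6,2014-04-19,17.52406,24.56569,17.51347,24.57459
7,2014-04-20,17.50359,24.56086,17.51045,24.58320
8,2014-04-21,17.51566,24.56018,17.52118,24.58638
9,2014-04-22,17.52421,24.54438,17.52635,24.58795
10,2014-04-23,17.52763,24.54746,17.54774,24.59577
11,2014-04-24,17.56850,24.59397,17.56258,25.00169
12,2014-04-25,17.51758,25.02057,17.51683,25.02055
13,2014-04-26,17.58648,25.05270,17.58578,25.05356
14,2014-04-27,18.02817,25.05320,18.03105,25.05504
15,2014-04-28,18.06645,25.07769,18.06569,25.07647
16,2014-04-29,18.08666,25.09166,18.06577,25.05941
17,2014-04-30,18.07551,25.11683,18.06859,25.06001
18,2014-05-01,18.09006,25.10678,18.06877,25.05097
19,2014-05-02,18.08346,25.12678,18.06336,25.05894
20,2014-05-03,18.09076,25.11720,18.06862,25.06003
21,2014-05-04,18.09602,25.11715,18.06757,25.05198
22,2014-05-05,18.09865,25.11074,,
23,2014-05-06,18.08029,25.13477,17.52323,25.03355
24,2014-05-07,18.09634,25.11622,17.56784,25.06875
25,2014-05-08,,,17.56390,25.06860
26,2014-05-09,17.51938,25.01550,17.58743,25.08636
27,2014-05-10,17.51466,25.02951,17.58523,25.08924
28,2014-05-11,17.55977,25.05397,17.56878,25.07593
29,2014-05-12,18.00076,25.07103,17.57795,25.07687
30,2014-05-13,17.52121,25.04718,17.59795,25.09988
31,2014-05-14,,,17.58056,25.07736
32,2014-05-15,17.54283,25.03360,17.52180,25.05044
33,2014-05-16,17.51535,25.02855,17.58675,25.08393
34,2014-05-17,17.52100,25.03476,17.59588,25.07721
35,2014-05-18,17.55674,25.02917,17.51152,25.02152
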