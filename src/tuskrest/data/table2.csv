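rd,date,sunset,sunrise,moonrise,moonset,moon_illum_pct,onset_m1,onset_m2,offset_m1,offset_m2,tst_h_m1,tst_h_m2,mse_h_m1,mse_h_m2,rsd_min_m1,rsd_min_m2,wbgt_min_c,wbgt_min_time,wbgt_onset_c_m1,wbgt_onset_c_m2,wbgt_offset_c_m1,wbgt_offset_c_m2,sld_km_m1,sld_km_m2,path_km_m1,path_km_m2,dist_m1_m2_km,tac_m1,tac_m2
1,2014-04-14,18:11,6:32,16:52,5:31,99.8,3:30,1:05,6:10,4:25,3.3,2.1,0.92,0.33,0,37,18.42,6:00,22.14,23.33,18.53,21.45,2.70,17.64,7.07,22.1,10.32,,
2,2014-04-15,18:11,6:32,17:31,6:27,100.0,1:35,2:40,6:20,4:55,4.2,1.2,1.58,0.42,69,0,17.7,6:40,21.14,19.7,17.65,19.13,2.20,9,6.84,16.35,3.98,206259,331423
3,2014-04-16,18:10,6:32,18:12,7:24,99.6,3:40,0:15,6:00,4:45,2.2,1.9,0.83,0.75,57,0,16.61,7:00,17.94,19.3,17.43,17.4,2.77,1.36,9.04,11.65,0.18,243346,305782
4,2014-04-17,18:10,6:32,18:57,8:22,96.8,,,,,,,,,0,0,17.59,2:50,,,,,,,,,,,
5,2014-04-18,18:09,6:33,19:46,9:22,91.6,1:05,1:40,3:45,3:55,2.4,2.0,1.75,0.83,0,0,17.92,5:20,20.12,19.45,18.57,18.4,29.26,29.07,54.92,51.49,1.30,514192,685219
6,2014-04-19,18:09,6:33,20:38,10:20,84.0,19:00,3:10,5:10,5:00,3.6,1.0,2.17,0.58,0,0,15.23,4:40,24.73,15.85,15.67,15.53,3.66,4.23,5.1,14.1,2.53,179234,409785
7,2014-04-20,18:08,6:33,21:35,11:17,74.5,2:55,3:05,6:00,5:55,2.9,2.8,1.42,1.33,0,28,14.64,5:30,17.75,17.66,15.83,15.83,4.02,1.61,13,10.53,4.16,396007,401057
8,2014-04-21,18:08,6:33,22:35,12:10,63.6,1:45,1:50,4:10,4:45,2.3,2.1,1.92,0.67,0,66,14.38,6:50,17.69,17.69,16.06,15.25,2.23,2.07,7.81,12.2,4.72,276659,360353
9,2014-04-22,18:07,6:34,23:36,13:01,51.8,2:25,23:50,4:55,5:55,2.2,3.3,1.75,1.25,122,0,16.02,1:40,17.11,19.69,18.31,16.82,3.21,0.98,19.21,10.85,7.71,297731,402186
10,2014-04-23,18:07,6:34,0:38,13:48,39.9,1:05,1:25,5:55,5:35,2.8,1.3,1.58,0.50,104,0,15.5,6:40,18.42,18.18,15.91,15.96,0.84,4.17,13.08,15.36,9.30,291464,368946
11,2014-04-24,18:06,6:34,1:39,14:32,28.6,2:15,4:50,3:15,5:30,0.8,0.5,0.42,0.17,0,0,18.66,3:30,20.25,20.48,18.67,19.84,11.16,2.95,15.67,16.39,1.74,292220,497660
12,2014-04-25,18:06,6:35,2:40,15:15,18.5,23:05,1:45,2:05,5:10,2.7,2.2,1.75,0.75,0,43,18.95,6:40,22.35,21.93,21.94,21.38,10.50,8.97,20.3,18.39,0.15,293754,393526
13,2014-04-26,18:05,6:35,3:40,15:57,10.3,0:05,2:00,5:55,5:25,2.8,0.4,1.33,0.17,46,0,20.98,4:20,23.21,22.16,21.97,21.78,13.91,14,22.02,20.76,0.21,324370,401567
14,2014-04-27,18:04,6:35,4:40,16:39,4.3,1:15,2:00,6:00,4:40,4.0,2.3,1.25,0.50,0,29,20.76,4:10,22.23,22.4,21.62,21.16,7.72,8.36,18.19,15.76,0.63,230105,408509
15,2014-04-28,18:04,6:35,5:39,17:22,0.9,4:00,2:30,6:05,5:45,1.9,2.2,1.75,0.33,18,0,14.11,5:00,15.12,16.86,14.47,14.39,8.26,7.44,16.69,16.33,0.25,283932,353663
16,2014-04-29,18:03,6:36,6:37,18:07,0.0,23:15,1:10,5:55,4:50,5.0,2.8,1.83,1.25,27,73,14.96,3:20,18.6,16.3,15.08,15.45,4.52,3.01,9.92,9.87,6.87,225604,323799
17,2014-04-30,18:03,6:36,7:35,18:54,1.7,2:30,0:25,6:15,4:10,4.5,3.0,3.75,1.58,93,47,12.95,6:40,14.02,14.71,13.48,14.87,4.88,0.54,8.42,10.49,10.12,237400,334396
18,2014-05-01,18:02,6:36,8:30,19:42,5.6,23:00,23:45,5:40,4:50,2.7,2.5,1.33,1.17,0,56,11.92,6:30,16.95,16.05,12.45,12.95,3.21,1.59,8.07,7.71,10.60,200556,353958
19,2014-05-02,18:02,6:37,9:23,20:32,11.3,0:30,1:00,6:10,5:45,4.0,3.1,1.58,1.75,0,0,13.32,6:40,16.28,16.08,13.72,13.82,3.71,1.73,11.95,10.63,12.52,233373,356489
20,2014-05-03,18:01,6:37,10:12,21:23,18.6,4:05,23:05,5:55,5:20,1.6,3.3,0.33,1.08,0,0,13.26,5:30,13.97,16.62,14.46,13.62,2.14,0.99,11.98,11.81,10.87,276196,306004
21,2014-05-04,18:01,6:37,10:59,22:13,27.0,2:30,2:45,6:00,4:50,2.9,1.5,1.50,0.92,0,0,11.18,6:30,15.95,16.26,11.46,12.23,0.97,1.43,11.01,7.88,12.63,239936,344733
22,2014-05-05,18:00,6:38,11:41,23:04,36.1,1:10,,6:00,,3.2,,1.42,,0,0,11.59,6:30,15.7,,11.81,,1.23,,10.96,,,237326,
23,2014-05-06,18:00,6:38,12:21,23:55,45.7,1:35,21:20,4:45,5:10,2.9,3.6,1.33,2.33,142,26,14.58,7:00,15.71,19.98,14.8,14.82,5.43,26.86,9.88,47.88,34.05,214613,673390
24,2014-05-07,17:59,6:38,12:59,0:45,55.5,2:50,2:00,5:35,5:45,2.5,1.4,1.08,0.42,0,0,16.55,6:50,19.56,19.91,17.4,17.28,4.41,10.32,9.92,20.14,25.12,253618,396942
25,2014-05-08,17:59,6:39,13:36,1:36,65.2,,2:00,,4:05,,1.3,,0.92,0,0,15.53,6:50,,18.43,,15.64,,0.73,,27.28,,,288319
26,2014-05-09,17:58,6:39,14:12,2:27,74.4,22:15,2:55,3:40,4:40,2.7,1.3,1.83,0.42,0,0,13.88,6:00,20.2,15.89,15.83,15.37,40.21,5.37,66.41,16.73,17.70,451563,370766
27,2014-05-10,17:57,6:39,14:48,3:20,82.8,3:35,2:00,5:00,6:20,1.2,1.6,0.83,0.42,0,0,13.27,6:50,14.85,15.14,13.61,13.3,2.62,0.65,9.09,11,16.76,353840,330753
28,2014-05-11,17:57,6:40,15:26,4:14,90.0,3:30,3:15,5:35,5:15,2.2,1.8,2.08,0.75,0,0,12.89,6:30,14.09,14.08,13.46,13.45,9.34,3.85,14.77,9.06,4.23,318708,338533
29,2014-05-12,17:56,6:40,16:06,5:11,95.5,4:05,3:20,4:55,3:35,0.8,0.3,0.67,0.25,0,0,15.05,7:00,17.77,17.71,16.22,17.89,8.19,1.7,19.05,28.3,4.34,276893,341444
30,2014-05-13,17:56,6:40,16:49,6:09,99.0,0:50,2:25,4:30,3:40,1.0,1.3,0.50,0.50,0,0,11.84,6:30,13.9,13.65,13.48,13.62,15.30,5.49,24.92,13.92,16.96,305825,359688
31,2014-05-14,17:55,6:41,17:35,7:10,100.0,,2:10,,4:35,,1.8,,1.33,0,0,8.34,6:40,,11.71,,8.95,,5.1,,8.83,,,312158
32,2014-05-15,17:55,6:41,18:29,8:10,99.9,22:50,0:00,5:45,3:45,1.3,3.4,0.83,1.08,0,48,9.22,6:30,13.88,16.27,9.55,11.04,9.52,11.83,31.95,19.8,4.90,634010,289410
33,2014-05-16,17:54,6:41,19:26,9:09,98.1,1:15,2:50,3:45,4:55,1.8,1.8,0.42,1.42,41,0,10.61,5:50,12.59,12.06,11.48,11.06,5.16,13.35,12.17,19.2,16.44,354017,363174
34,2014-05-17,17:54,6:42,20:26,10:06,93.5,1:35,3:15,3:05,3:50,0.4,0.6,0.08,0.33,0,0,11.16,6:50,13.93,12.82,13.2,12.07,1.51,2.06,6.77,14.02,15.74,319731,329249
35,2014-05-18,17:53,6:42,21:29,11:03,86.3,21:40,2:20,3:50,5:50,0.6,1.3,0.17,0.50,0,0,12.52,4:00,18.08,14.37,12.62,12.97,6.62,18.4,7.78,24.97,8.38,268639,364092
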