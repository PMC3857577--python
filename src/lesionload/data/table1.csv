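patient_id,gender,age_years,months_post_stroke,ravens,word_discrimination_pct,commands_pct,word_repetition_pct,bnt,words_per_min,cius_per_min,lesion_volume_cc,af_ll_cc,fgm_ll_cc,af_fgm_ll_cc,emc_ll_cc,uf_ll_cc
1,F,32,10,34,70.3,53.3,10.0,7,29.0,19.0,143.25,4.24,15.39,19.22,4.61,4.73
2,F,37,19,36,100.0,100.0,60.0,13,77.0,56.0,184.09,1.48,13.32,14.70,2.59,2.61
3,M,68,15,N/A,N/A,60.0,100.0,1,86.0,29.0,42.46,0.24,2.19,2.41,2.22,2.72
4,M,54,8,36,90.5,100.0,90.0,11,41.8,24.5,42.61,3.35,3.78,6.18,1.29,2.71
5,F,71,96,25,68.9,60.0,0.0,0,1.3,0.9,197.24,9.75,20.16,24.58,5.14,2.95
6,M,29,120,32,N/A,N/A,N/A,0,2.1,0.9,191.20,9.72,24.98,29.83,4.84,6.19
7,M,47,13,33,94.6,86.7,70.0,12,17.9,3.8,169.24,4.35,12.58,14.33,2.79,4.00
8,M,74,6,24,71.6,53.3,40.0,1,11.6,0.9,123.77,4.27,13.51,15.04,0.14,0.00
9,M,55,60,30,45.5,54.6,25.0,1,4.8,0.6,295.73,11.69,26.74,35.09,5.42,6.22
10,M,57,53,28,N/A,83.3,63.6,5,4.0,0.3,123.16,3.58,11.63,18.03,1.77,0.00
11,M,62,22,32,98.6,100.0,40.0,5,3.5,1.5,42.05,4.27,4.37,6.99,1.68,0.37
12,M,56,29,34,64.9,66.7,30.0,7,10.2,0.5,152.87,9.46,17.15,23.53,3.55,3.81
13,M,71,14,29,100.0,86.7,10.0,8,8.3,2.6,73.40,3.35,7.59,9.45,1.58,2.21
14,M,35,9,35,94.0,100.0,50.0,4,5.2,0.3,198.76,5.18,13.00,14.17,2.14,2.72
15,F,48,12,30,60.0,58.3,60.0,0,2.5,0.4,260.82,8.28,19.47,25.62,4.74,5.90
16,M,44,44,35,100.0,75.0,60.0,14,17.2,7.2,259.45,6.81,26.85,24.03,4.06,5.73
17,M,56,18,28,82.4,20.0,25.0,0,19.3,0.4,136.78,6.74,18.68,21.74,3.74,3.91
18,M,55,7,31,91.9,26.7,30.0,5,7.3,2.0,249.80,10.82,25.40,31.89,4.50,5.86
19,F,54,12,33,87.8,70.0,20.0,6,21.3,2.4,127.98,3.78,9.11,9.57,0.90,0.46
20,M,63,24,36,79.7,33.3,70.0,4,19.2,3.6,112.30,6.78,17.41,23.26,3.06,3.36
21,M,53,25,36,62.2,60.0,70.0,5,21.3,5.9,212.35,7.99,23.70,27.91,4.70,6.37
22,M,60,21,24,66.2,53.3,70.0,1,0.8,0.1,263.11,10.58,22.00,28.04,4.32,5.88
23,M,67,9,35,62.2,46.7,10.0,0,9.8,0.1,155.14,10.29,19.76,25.70,4.89,6.23
24,M,65,108,34,91.9,100.0,20.0,3,36.5,5.1,188.74,9.36,15.88,21.63,5.13,6.25
25,M,71,66,20,N/A,57.1,100.0,3,12.6,1.3,250.30,7.04,19.59,20.50,3.40,3.54
26,M,62,25,30,43.2,60.0,50.0,0,24.2,0.4,145.40,6.15,19.25,21.57,2.71,5.51
27,M,47,18,27,83.8,66.7,40.0,2,12.6,2.6,241.38,9.40,23.69,27.30,2.18,0.29
28,M,63,6,20,82.4,73.3,40.0,0,2.9,0.3,226.59,5.95,17.10,17.79,3.28,3.33
29,M,62,77,35,58.1,60.0,10.0,0,28.8,1.0,157.77,9.88,16.15,24.50,4.65,5.97
30,M,56,15,26,86.5,50.0,40.0,3,17.4,1.7,75.82,4.92,6.04,9.45,2.73,3.25
31,M,62,14,36,97.3,93.3,0.0,0,2.3,0.6,71.18,7.09,6.67,10.12,3.16,2.82
32,M,45,11,32,28.4,60.0,50.0,0,25.0,0.4,246.65,10.94,26.26,31.49,3.69,3.82
33,F,62,15,32,81.1,86.7,20.0,0,7.9,0.3,108.30,2.96,10.34,8.90,2.87,5.18
34,M,59,16,31,33.8,33.3,90.0,1,29.8,1.3,196.87,11.25,21.34,28.05,3.74,4.53
35,M,51,12,33,70.3,33.3,10.0,0,6.1,0.2,63.47,5.63,8.67,11.26,4.01,1.61
36,F,66,27,34,89.2,73.3,40.0,8,19.8,8.0,297.27,6.89,22.82,27.33,3.75,6.48
37,F,69,12,21,N/A,71.4,71.4,2,21.5,0.8,94.22,4.50,10.04,11.87,0.16,0.03
38,F,51,17,34,N/A,100.0,75.0,0,48.1,1.8,199.78,7.70,16.45,19.58,4.80,5.79
39,M,51,9,33,39.2,33.3,70.0,2,35.3,0.3,176.47,8.66,20.08,24.95,4.50,5.23
40,M,50,13,35,100.0,100.0,90.0,14,24.4,8.9,57.42,3.44,9.54,13.75,0.37,0.37
41,F,68,26,21,83.3,71.4,N/A,9,86.4,54.2,17.70,0.73,0.07,0.75,0.60,0.00
42,M,45,11,N/A,N/A,N/A,N/A,15,38.0,32.9,100.84,2.75,4.75,5.72,0.14,0.00
43,M,64,92,36,N/A,N/A,N/A,15,47.5,28.8,72.10,5.20,5.34,8.27,2.04,2.86
44,M,61,13,35,100.0,100.0,N/A,15,77.9,63.5,12.68,0.07,0.46,0.60,0.00,0.00
45,M,74,65,34,97.3,86.7,90.0,14,39.8,23.3,54.09,3.70,5.56,8.32,1.43,1.43
46,M,56,79,34,73.0,86.7,80.0,12,29.3,13.5,110.32,6.49,9.71,16.02,4.38,5.51
47,M,45,15,36,94.6,100.0,90.0,15,50.8,29.2,15.23,0.08,0.52,0.69,0.63,0.01
48,M,45,11,36,97.3,93.3,90.0,14,31.2,18.8,84.20,2.70,10.78,15.37,2.55,4.22
49,M,58,12,N/A,98.6,93.3,80.0,10,58.6,27.4,57.16,2.41,4.58,5.99,2.62,3.34
50,M,65,18,N/A,89.2,87.5,100.0,13,50.8,37.0,14.37,1.24,0.08,1.05,0.42,0.14
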