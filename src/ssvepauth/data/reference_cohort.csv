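subject,lf3_acc_pct,lf3_time_s,hf3_acc_pct,hf3_time_s,lf1_acc_pct,lf1_time_s,hf1_acc_pct,hf1_time_s
1,94,25.64,100,12.74,97,16.69,100,56.40
2,97,16.99,100,27.10,91,72.25,75,62.08
3,100,12.44,100,42.16,97,16.58,91,113.30
4,100,16.39,100,15.23,100,27.09,100,48.36
5,91,28.39,97,125.75,100,22.69,97,48.78
6,100,15.00,97,20.59,94,40.56,100,76.21
7,97,28.18,97,95.75,100,34.14,94,79.13
8,94,44.29,100,65.11,94,73.65,100,64.83
9,97,28.68,97,51.45,100,27.98,81,52.14
10,94,10.09,100,15.66,91,36.93,100,10.61
11,100,14.30,100,50.66,94,37.00,78,246.66
12,97,8.25,97,10.78,97,8.65,97,32.83
13,100,9.54,100,11.69,100,9.20,100,36.46
14,94,9.41,100,32.16,97,20.65,94,374.06
15,97,10.26,97,25.59,100,13.16,100,14.33
16,88,23.29,100,63.98,94,14.16,97,55.68
17,100,11.90,100,8.39,100,18.50,100,7.93
18,100,18.10,97,104.90,100,43.14,88,188.95
19,94,11.83,100,15.55,91,13.64,100,20.30
20,100,8.20,100,7.81,91,11.65,97,10.26
21,100,9.78,100,7.88,94,11.28,100,9.83
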