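number,act,pls_pred,pls_rep,pls_press,enpls_pred,enpls_rep,enpls_press
1,108.33,100.04,-8.29,68.72,95.66,-12.67,160.53
2,105.95,109.26,3.31,10.96,101.16,-4.79,22.94
3,107.54,121.08,13.54,183.33,150.84,43.30,1874.89
4,100.00,95.54,-4.46,19.89,110.57,10.57,111.72
5,100.79,94.68,-6.11,37.33,97.03,-3.76,14.14
6,89.68,103.86,14.18,201.07,101.68,12.00,144.00
7,91.27,105.41,14.14,199.94,87.64,-3.63,13.18
8,85.32,121.30,35.98,1294.56,103.43,18.11,327.97
9,101.87,85.91,-15.96,254.72,104.86,2.99,8.94
10,102.25,111.26,9.01,81.18,104.34,2.09,4.37
11,108.61,96.89,-11.72,137.36,112.05,3.44,11.83
12,116.10,102.6,-13.50,182.25,107.22,-8.88,78.85
13,91.76,96.31,4.55,20.70,90.37,-1.39,1.93
14,92.13,99.56,7.43,55.20,100.61,8.48,71.91
15,82.83,82.06,-0.77,0.59,86.56,3.73,13.91
16,82.53,85.69,3.16,9.99,82.04,-0.49,0.24
17,115.58,120.84,5.26,27.67,122.50,6.92,47.89
18,120.29,115.73,-4.56,20.79,125.46,5.17,26.73
19,135.14,126.63,-8.51,72.42,136.89,1.75,3.06
20,126.45,110.55,-15.90,252.81,121.62,-4.83,23.33
21,122.46,104.37,-18.09,327.25,116.8,-5.66,32.04
22,121.38,129.29,7.91,62.57,113.11,-8.27,68.39
23,119.20,122.39,3.19,10.18,133.17,13.97,195.16
24,102.41,120.91,18.50,342.25,99.67,-2.74,7.51
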