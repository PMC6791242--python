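voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n
0,0,0,100,0,20
5,0.6,3,100.57,6.52,20
5,0.6,6,105.89,10.51,20
5,0.6,9,107.64,8.97,20
5,0.8,3,103.4,5.91,20
5,0.8,6,111.86,6.87,20
5,0.8,9,112.64,3.53,20
5,1,3,105.17,7.17,20
5,1,6,111.91,6.09,20
5,1,9,114.33,2.74,20
5,1.2,3,100.92,8.18,20
5,1.2,6,101.8,9.8,20
5,1.2,9,102.18,6.7,20
6,0.6,3,101.15,16.08,20
6,0.6,6,105.94,14.42,20
6,0.6,9,106.63,12.5,20
6,0.8,3,104.81,12.95,20
6,0.8,6,114.28,7.7,20
6,0.8,9,118.55,5.75,20
6,1,3,107.72,14.07,20
6,1,6,114.45,7.28,20
6,1,9,119.57,3.85,20
6,1.2,3,100.71,13.13,20
6,1.2,6,101.75,9.43,20
6,1.2,9,100.67,10.46,20
7,0.6,3,102.8,10.92,20
7,0.6,6,109.02,10.41,20
7,0.6,9,108.78,9.49,20
7,0.8,3,102.84,10.81,20
7,0.8,6,114.06,7.33,20
7,0.8,9,116.21,6.41,20
7,1,3,103.94,6.54,20
7,1,6,114.64,6.6,20
7,1,9,116.61,7.49,20
7,1.2,3,100.59,7.15,20
7,1.2,6,101.73,10.3,20
7,1.2,9,102.36,9.62,20
8,0.6,3,101.57,7.73,20
8,0.6,6,104.79,16.66,20
8,0.6,9,103.17,13.78,20
8,0.8,3,102.46,10.56,20
8,0.8,6,107.28,18.14,20
8,0.8,9,106.05,14.84,20
8,1,3,102.34,12.14,20
8,1,6,106.86,20.24,20
8,1,9,105.95,14.88,20
8,1.2,3,101.48,9.82,20
8,1.2,6,102.77,16.21,20
8,1.2,9,101.17,10.47,20
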