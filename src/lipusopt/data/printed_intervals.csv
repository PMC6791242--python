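voltage_v,frequency_mhz,duration_min,ci_low_pct,ci_high_pct,p_value,flag
5,0.6,3,97.52,103.62,0.699,ns
5,0.6,6,100.97,110.81,0.017,*
5,0.6,9,103.44,111.84,0.0005,**
5,0.8,3,100.63,106.16,0.014,*
5,0.8,6,108.64,115.07,2.64e-09,**
5,0.8,9,110.99,114.29,1.66e-18,**
5,1,3,101.81,108.53,0.003,**
5,1,6,109.06,114.76,1.22e-10,**
5,1,9,113.04,115.61,3.90e-24,**
5,1.2,3,97.09,104.74,0.619,ns
5,1.2,6,97.21,106.38,0.418,ns
5,1.2,9,99.05,105.32,0.153,ns
6,0.6,3,93.62,108.68,0.751,ns
6,0.6,6,99.19,112.69,0.073,ns
6,0.6,9,100.78,112.49,0.023,*
6,0.8,3,98.75,110.87,0.105,ns
6,0.8,6,110.68,117.89,4.70e-10,**
6,0.8,9,115.87,121.24,5.15e-17,**
6,1,3,101.13,114.3,0.019,*
6,1,6,111.04,117.86,8.56e-11,**
6,1,9,117.77,121.37,1.00e-23,**
6,1.2,3,94.57,106.86,0.81,ns
6,1.2,6,97.33,106.16,0.412,ns
6,1.2,9,95.77,105.56,0.777,ns
7,0.6,3,97.69,107.91,0.259,ns
7,0.6,6,104.15,113.9,0.0004,**
7,0.6,9,104.34,113.22,0.0002,**
7,0.8,3,97.78,107.9,0.248,ns
7,0.8,6,110.63,117.49,1.99e-10,**
7,0.8,9,113.21,119.21,9.86e-14,**
7,1,3,100.88,106.1,0.01,*
7,1,6,111.55,117.73,4.24e-12,**
7,1,9,113.1,120.11,4.28e-12,**
7,1.2,3,97.24,103.94,0.715,ns
7,1.2,6,96.91,106.55,0.458,ns
7,1.2,9,97.85,106.86,0.28,ns
8,0.6,3,97.95,105.2,0.368,ns
8,0.6,6,96.99,112.58,0.206,ns
8,0.6,9,96.72,109.62,0.31,ns
8,0.8,3,97.51,107.4,0.305,ns
8,0.8,6,98.79,115.77,0.081,ns
8,0.8,9,99.1,112.1,0.076,ns
8,1,3,96.66,108.02,0.394,ns
8,1,6,97.38,116.33,0.138,ns
8,1,9,98.99,112.91,0.082,ns
8,1.2,3,96.88,106.07,0.505,ns
8,1.2,6,95.18,110.35,0.45,ns
8,1.2,9,96.27,106.07,0.62,ns
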