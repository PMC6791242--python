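voltage_v,frequency_mhz,intensity_mw_cm2
5,0.6,13.9
5,0.8,3.4
5,1,33.7
5,1.2,3.7
6,0.6,19.3
6,0.8,4.7
6,1,48.2
6,1.2,5.1
7,0.6,28.9
7,0.8,6.8
7,1,53.9
7,1.2,8
8,0.6,37.3
8,0.8,8.5
8,1,69.3
8,1.2,10
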