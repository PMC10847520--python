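slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.2751,-0.6995,-0.6969,-0.5572
3,0.3265,-0.0759,-0.1802,-0.1835,-0.1466
4,0.4388,-0.0104,-0.0400,-0.0421,-0.0309
5,0.5510,0.0088,0.0038,0.0032,0.0053
6,0.6633,-0.0023,-0.0056,-0.0058,-0.0046
7,0.7755,0.0111,0.0074,0.0071,0.0085
8,0.8878,0.0078,0.0043,0.0039,0.0053
9,1.0000,-0.0075,-0.0108,-0.0112,-0.0098
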