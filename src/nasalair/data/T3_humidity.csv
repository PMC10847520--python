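slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.2595,-0.2610,-0.2645,-0.2616
3,0.3265,-0.0802,-0.0828,-0.0844,-0.0825
4,0.4388,-0.0140,-0.0171,-0.0179,-0.0163
5,0.5510,0.0059,0.0025,0.0022,0.0035
6,0.6633,0.0075,0.0043,0.0039,0.0052
7,0.7755,0.0075,0.0043,0.0039,0.0052
8,0.8878,0.0049,0.0016,0.0011,0.0025
9,1.0000,-0.0049,-0.0083,-0.0086,-0.0073
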