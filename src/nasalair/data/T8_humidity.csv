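slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.3419,-0.3440,-0.3459,-0.3439
3,0.3265,-0.0841,-0.0873,-0.0889,-0.0868
4,0.4388,-0.0130,-0.0164,-0.0173,-0.0156
5,0.5510,0.0085,0.0047,0.0043,0.0058
6,0.6633,-0.0020,-0.0058,-0.0058,-0.0045
7,0.7755,0.0111,0.0072,0.0069,0.0084
8,0.8878,0.0078,0.0040,0.0039,0.0053
9,1.0000,-0.0075,-0.0110,-0.0117,-0.0101
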