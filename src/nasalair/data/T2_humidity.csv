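slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.1806,-0.4431,-0.4453,-0.4460,-0.4448
3,0.2977,-0.0662,-0.0693,-0.0708,-0.0688
4,0.4147,-0.0042,-0.0076,-0.0082,-0.0067
5,0.5318,0.0101,0.0065,0.0063,0.0076
6,0.6488,0.0117,0.0081,0.0078,0.0092
7,0.7659,0.0121,0.0083,0.0080,0.0095
8,0.8829,0.0121,0.0083,0.0080,0.0095
9,1.0000,-0.0036,-0.0072,-0.0076,-0.0061
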