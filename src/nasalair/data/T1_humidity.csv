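slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.1806,-0.5143,-0.5159,-0.5166,-0.5156
3,0.2977,-0.0988,-0.1012,-0.1032,-0.1011
4,0.4147,-0.0137,-0.0169,-0.0177,-0.0161
5,0.5318,0.0085,0.0049,0.0047,0.0061
6,0.6488,0.0108,0.0074,0.0069,0.0084
7,0.7659,0.0111,0.0076,0.0073,0.0087
8,0.8829,0.0111,0.0074,0.0071,0.0085
9,1.0000,-0.0026,-0.0061,-0.0063,-0.0050
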