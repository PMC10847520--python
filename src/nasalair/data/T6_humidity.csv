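slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.2764,-0.2783,-0.2804,-0.2784
3,0.3265,-0.0740,-0.0767,-0.0784,-0.0764
4,0.4388,-0.0111,-0.0142,-0.0149,-0.0134
5,0.5510,0.0075,0.0043,0.0039,0.0052
6,0.6633,-0.0026,-0.0061,-0.0063,-0.0050
7,0.7755,0.0101,0.0067,0.0065,0.0078
8,0.8878,0.0068,0.0036,0.0032,0.0046
9,1.0000,-0.0081,-0.0115,-0.0119,-0.0105
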