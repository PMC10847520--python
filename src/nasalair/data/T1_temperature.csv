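slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.1806,-0.5035,-0.5027,-0.5058,-0.5040
3,0.2977,-0.0961,-0.0953,-0.0978,-0.0964
4,0.4147,-0.0193,-0.0193,-0.0196,-0.0194
5,0.5318,-0.0017,-0.0020,-0.0017,-0.0018
6,0.6488,-0.0002,0.0000,-0.0001,-0.0001
7,0.7659,0.0000,0.0000,0.0000,0.0000
8,0.8829,0.0000,0.0000,-0.0001,0.0000
9,1.0000,-0.0133,-0.0133,-0.0129,-0.0132
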