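slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.1806,-0.4338,-0.4327,-0.4356,-0.4340
3,0.2977,-0.0669,-0.0660,-0.0681,-0.0670
4,0.4147,-0.0122,-0.0120,-0.0125,-0.0122
5,0.5318,-0.0011,-0.0013,-0.0011,-0.0012
6,0.6488,-0.0001,0.0000,-0.0001,-0.0001
7,0.7659,0.0000,0.0000,0.0000,0.0000
8,0.8829,0.0000,0.0000,0.0000,0.0000
9,1.0000,-0.0151,-0.0153,-0.0147,-0.0151
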