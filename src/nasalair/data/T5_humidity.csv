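slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.3250,-0.3267,-0.3299,-0.3272
3,0.3265,-0.0903,-0.0934,-0.0950,-0.0929
4,0.4388,-0.0160,-0.0193,-0.0203,-0.0185
5,0.5510,0.0068,0.0029,0.0026,0.0041
6,0.6633,0.0081,0.0045,0.0043,0.0057
7,0.7755,0.0085,0.0047,0.0043,0.0058
8,0.8878,0.0059,0.0020,0.0017,0.0032
9,1.0000,-0.0042,-0.0079,-0.0084,-0.0068
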