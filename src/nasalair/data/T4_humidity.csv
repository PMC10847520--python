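slice,distance,hum_28_60,hum_40_05,hum_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.6802,-0.6822,-0.6809,-0.6811
3,0.3265,-0.1842,-0.1863,-0.1895,-0.1867
4,0.4388,-0.0401,-0.0430,-0.0451,-0.0427
5,0.5510,0.0055,0.0020,0.0015,0.0030
6,0.6633,0.0085,0.0047,0.0043,0.0058
7,0.7755,0.0085,0.0049,0.0045,0.0060
8,0.8878,0.0059,0.0022,0.0017,0.0033
9,1.0000,-0.0039,-0.0076,-0.0080,-0.0065
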