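slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.2496,-0.2470,-0.2535,-0.2501
3,0.3265,-0.0785,-0.0772,-0.0804,-0.0787
4,0.4388,-0.0200,-0.0200,-0.0205,-0.0202
5,0.5510,-0.0049,-0.0047,-0.0047,-0.0048
6,0.6633,-0.0031,-0.0033,-0.0030,-0.0032
7,0.7755,-0.0034,-0.0033,-0.0033,-0.0034
8,0.8878,-0.0066,-0.0067,-0.0064,-0.0065
9,1.0000,-0.0171,-0.0173,-0.0166,-0.0170
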