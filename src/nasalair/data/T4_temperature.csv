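slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.6733,-0.6718,-0.6738,-0.6730
3,0.3265,-0.1785,-0.1764,-0.1818,-0.1789
4,0.4388,-0.0432,-0.0426,-0.0450,-0.0436
5,0.5510,-0.0056,-0.0053,-0.0056,-0.0055
6,0.6633,-0.0032,-0.0033,-0.0031,-0.0032
7,0.7755,-0.0034,-0.0033,-0.0033,-0.0034
8,0.8878,-0.0066,-0.0067,-0.0064,-0.0065
9,1.0000,-0.0171,-0.0173,-0.0166,-0.0170
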