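slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.3307,-0.3293,-0.3341,-0.3314
3,0.3265,-0.0841,-0.0833,-0.0861,-0.0845
4,0.4388,-0.0197,-0.0193,-0.0204,-0.0198
5,0.5510,-0.0031,-0.0033,-0.0031,-0.0032
6,0.6633,-0.0136,-0.0133,-0.0132,-0.0134
7,0.7755,-0.0010,-0.0007,-0.0009,-0.0008
8,0.8878,-0.0048,-0.0047,-0.0046,-0.0047
9,1.0000,-0.0208,-0.0213,-0.0202,-0.0208
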