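slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.2650,-0.2633,-0.2687,-0.2657
3,0.3265,-0.0736,-0.0727,-0.0755,-0.0739
4,0.4388,-0.0173,-0.0173,-0.0179,-0.0175
5,0.5510,-0.0031,-0.0033,-0.0031,-0.0032
6,0.6633,-0.0133,-0.0133,-0.0129,-0.0132
7,0.7755,-0.0008,-0.0007,-0.0007,-0.0007
8,0.8878,-0.0047,-0.0047,-0.0045,-0.0046
9,1.0000,-0.0205,-0.0207,-0.0198,-0.0203
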