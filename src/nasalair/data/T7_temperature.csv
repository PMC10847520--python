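slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.6881,-0.6887,-0.6890,-0.6886
3,0.3265,-0.1763,-0.1720,-0.1770,-0.1751
4,0.4388,-0.0409,-0.0400,-0.0424,-0.0411
5,0.5510,-0.0038,-0.0040,-0.0040,-0.0039
6,0.6633,-0.0141,-0.0133,-0.0130,-0.0135
7,0.7755,-0.0008,-0.0007,-0.0007,-0.0007
8,0.8878,-0.0047,-0.0047,-0.0045,-0.0046
9,1.0000,-0.0210,-0.0207,-0.0198,-0.0205
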