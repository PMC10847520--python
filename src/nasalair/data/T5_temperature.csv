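slice,distance,temp_28_60,temp_40_05,temp_05_10,average
1,0.0000,-1.0000,-1.0000,-1.0000,-1.0000
2,0.2143,-0.3153,-0.3129,-0.3189,-0.3157
3,0.3265,-0.0890,-0.0879,-0.0910,-0.0893
4,0.4388,-0.0224,-0.0220,-0.0230,-0.0225
5,0.5510,-0.0049,-0.0047,-0.0048,-0.0048
6,0.6633,-0.0034,-0.0033,-0.0033,-0.0034
7,0.7755,-0.0036,-0.0033,-0.0035,-0.0035
8,0.8878,-0.0067,-0.0067,-0.0065,-0.0066
9,1.0000,-0.0174,-0.0180,-0.0170,-0.0175
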