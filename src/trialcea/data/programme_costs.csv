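stage,label,amount,parental
1,Materials,6694,0
1,Training,38079,0
2,Teaching,27877,0
2,Facilitator (parental component),13250,1
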