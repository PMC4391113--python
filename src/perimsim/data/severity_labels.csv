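patient,full_threshold,sita_standard,sita_fast
1,Severe,Severe,Severe
2,Moderate,Moderate,Moderate
3,Nil,Nil,Nil
4,Nil,Nil,Nil
5,Moderate,Moderate,Moderate
6,Nil,Nil,Nil
7,Mild,Mild,Nil
8,Nil,Nil,Nil
9,Nil,Nil,Nil
10,Nil,Nil,Nil
11,Severe,Severe,Severe
12,Nil,Nil,Nil
13,Nil,Nil,Nil
14,Severe,Severe,Severe
15,Nil,Severe,Moderate
16,Nil,Nil,Nil
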