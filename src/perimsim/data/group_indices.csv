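algorithm,visit,index,mean,sd
full_threshold,2,MS,24.30,5.28
sita_standard,2,MS,25.30,5.66
sita_fast,2,MS,26.14,5.36
full_threshold,3,MS,24.05,5.04
sita_standard,3,MS,25.30,6.29
sita_fast,3,MS,25.56,5.34
full_threshold,2,MD,-4.24,4.00
sita_standard,2,MD,-4.25,4.46
sita_fast,2,MD,-3.90,4.76
full_threshold,3,MD,-4.89,3.79
sita_standard,3,MD,-5.06,4.98
sita_fast,3,MD,-4.34,4.25
full_threshold,2,PSD,4.70,3.67
sita_standard,2,PSD,4.78,3.91
sita_fast,2,PSD,3.99,3.30
full_threshold,3,PSD,4.89,3.51
sita_standard,3,PSD,4.95,3.97
sita_fast,3,PSD,4.63,3.64
full_threshold,2,duration_s,937.0,157.9
sita_standard,2,duration_s,449.0,80.9
sita_fast,2,duration_s,279.4,79.2
full_threshold,3,duration_s,956.6,165.1
sita_standard,3,duration_s,464.1,99.4
sita_fast,3,duration_s,282.3,67.3
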