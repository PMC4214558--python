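# Same rate constants at the in vivo stoichiometry CheA:CheY1:CheY2 =
# 1.5:20:20 uM.
k1: 1.0
k2: 100.0
ka: 1.0
kS: 1.0
krS: 0.01
kM: 2.0
krM: 1.0
khS: 0.056
khM: 0.066
HK_tot: 1.5
RR1_tot: 20.0
RR2_tot: 20.0
ATP: 10.0
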