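# S. meliloti CheA/CheY1/CheY2 rate constants with the in vitro totals
# (10:2.5:2.5 uM).  ka is the signal and is varied by the analyses; the
# value below is only the resting default.  ATP is clamped well below
# the HK.ATP Kd (k2/k1 = 100 uM) so the complex stays a minor,
# quasi-equilibrated species and ka is the kinetically limiting signal.
k1: 1.0
k2: 100.0
ka: 1.0
kS: 1.0
krS: 0.01
kM: 2.0
krM: 1.0
khS: 0.056
khM: 0.066
HK_tot: 10.0
RR1_tot: 2.5
RR2_tot: 2.5
ATP: 10.0
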