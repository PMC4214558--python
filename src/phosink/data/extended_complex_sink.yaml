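# Extended-model example: phosphotransfer through explicit complexes
# makes the signal-response curve sigmoidal even though the reverse
# sink transfer outpaces the forward one (kS/krS = 0.83 < 1), which is
# impossible in the bimolecular model.  The relaxed complex-model
# condition kS/krS > (kyM - kyS)/kyrS holds here.
k1: 1.0
k2: 100.0
ka: 1.0
kS: 1.0
krS: 1.2
kM: 2.0
krM: 1.0
khS: 0.056
khM: 0.066
kyS: 20.0
kyM: 0.05
kyrS: 2.0
HK_tot: 10.0
RR1_tot: 2.5
RR2_tot: 2.5
ATP: 10.0
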