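# Partial parameter set for the yeast osmoregulation sink (SLN1 ->
# SSK1/SKN7).  Only the published sink-branch rates and the sink total
# are measured; the remaining fields keep the S. meliloti defaults and
# should be overridden by the user where better values exist.
k1: 1.0
k2: 100.0
ka: 1.0
kS: 66.67
krS: 0.01
kM: 1.0
krM: 1.0
khS: 0.5
khM: 0.066
HK_tot: 10.0
RR1_tot: 1.5
RR2_tot: 2.5
ATP: 10.0
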