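# Synapse registry. One aggregate gating variable s per (cell, kind); a presynaptic
# spike increments s by multiplicity * alpha * increment_scaling, s decays with tau
# (NMDA uses the saturating two-variable scheme of Compte et al. 2003 instead).
# I_syn = g * s * (V - E); excitatory kinds target the dendrite, inhibitory the soma.
# Cortical g values are the network defaults; cortico-hippocampal g values are
# calibrated so a unitary event reproduces the target EPSP/EPSC on a resting cell
# (see docs/methods.md); hippocampal-internal g values are network calibration.
kind	g_nS	E_mV	tau_ms	alpha	increment_scaling	target	source
ctx_ampa_pp	4.15	0.0	2.0	5.5	0.333333333333	dend	alpha calibrated to the SO regime; g fixed network value
ctx_nmda_pp	0.225	0.0	100.0	6.0	0.333333333333	dend	alpha calibrated to the SO regime; g fixed network value
ctx_ampa_pi	0.5	0.0	2.0	4.0	0.333333333333	soma	alpha calibrated to the SO regime; g fixed network value
ctx_nmda_pi	0.11	0.0	100.0	6.0	0.333333333333	soma	alpha calibrated to the SO regime; g fixed network value
ctx_gaba_ip	4.15	-75.0	10.0	2.2	0.5	soma	Compte et al. 2003 g; reversal lowered to -75 mV
ctx_gaba_ii	0.165	-75.0	10.0	2.2	0.5	soma	Compte et al. 2003 g; reversal lowered to -75 mV
MF_to_PY	0.6513	0.0	2.0	70.0	1.0	dend	alpha: mossy-fiber unitary scheme; g calibrated to 5 mV EPSP
MF_to_IN	1.0198	0.0	2.0	0.5	1.0	soma	g calibrated to 0.25 mV EPSP / 30 pA EPSC
TA_to_PY	1.1846	0.0	2.0	2.0	1.0	dend	g calibrated to 0.16 mV EPSP / 0.13 nA EPSC
TA_to_IN	1.0446	0.0	2.0	2.0	1.0	soma	g calibrated to 1 mV EPSP
ca3_ampa_pp	0.5	0.0	2.0	1.0	1.0	dend	network calibration (recurrent CA3 excitation)
ca3_ampa_pi	5.0	0.0	2.0	1.0	1.0	soma	network calibration (fast feedback-IN recruitment)
ca3_gaba_ip	12.0	-75.0	5.0	1.0	1.0	soma	network calibration (burst truncation)
schaffer_py	0.07	0.0	2.0	1.0	1.0	dend	network calibration (per-synapse; multiplicity per target cell)
schaffer_in	0.07	0.0	2.0	1.0	1.0	soma	network calibration (fixed multiplicity per connection)
ca1_ampa_pi	7.0	0.0	2.0	1.0	1.0	soma	network calibration (feedback-IN recruitment)
ca1_gaba_ip	11.0	-75.0	2.0	1.0	1.0	soma	network calibration (fast perisomatic inhibition)
ca1_gaba_ii	2.0	-75.0	2.0	1.0	1.0	soma	network calibration (fast recurrent inhibition)
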