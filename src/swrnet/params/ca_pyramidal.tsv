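# CA3/CA1 pyramidal cell: two-compartment Pinsky-Rinzel cell, expressed in
# physiological membrane potential (the original model's voltage scale is shifted
# by -60 mV so that rest sits near -60 mV and spike detection at +10 mV applies).
# Somatic: INa, IK-DR; dendritic: ICa, IK-C, IK-AHP.
name	value	units	source
Cm	3.0	uF/cm2	Pinsky & Rinzel 1994
area_total	0.03	mm2	this package (sets nS-to-density conversion; see docs/methods.md)
p_soma	0.5	1	Pinsky & Rinzel 1994
g_c	2.1	mS/cm2	Pinsky & Rinzel 1994
g_L	0.1	mS/cm2	Pinsky & Rinzel 1994
E_L	-60.0	mV	Pinsky & Rinzel 1994 (shifted)
g_Na	30.0	mS/cm2	Pinsky & Rinzel 1994
E_Na	60.0	mV	Pinsky & Rinzel 1994 (shifted)
g_KDR	15.0	mS/cm2	Pinsky & Rinzel 1994
E_K	-75.0	mV	Pinsky & Rinzel 1994 (shifted)
g_Ca	10.0	mS/cm2	Pinsky & Rinzel 1994
E_Ca	80.0	mV	Pinsky & Rinzel 1994 (shifted)
g_KC	15.0	mS/cm2	Pinsky & Rinzel 1994
g_KAHP	0.8	mS/cm2	Pinsky & Rinzel 1994
spike_threshold	10.0	mV	presynaptic spike detection threshold
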