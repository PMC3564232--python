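# CA3/CA1 perisomatic (basket) interneuron: single-compartment Wang-Buzsaki cell.
name	value	units	source
Cm	1.0	uF/cm2	Wang & Buzsaki 1996
area	0.02	mm2	this package (same convention as the cortical interneuron)
g_L	0.1	mS/cm2	Wang & Buzsaki 1996
E_L	-65.0	mV	Wang & Buzsaki 1996
g_Na	35.0	mS/cm2	Wang & Buzsaki 1996
E_Na	55.0	mV	Wang & Buzsaki 1996
g_K	9.0	mS/cm2	Wang & Buzsaki 1996
E_K	-90.0	mV	Wang & Buzsaki 1996
phi	5.0	1	Wang & Buzsaki 1996
spike_threshold	10.0	mV	presynaptic spike detection threshold
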