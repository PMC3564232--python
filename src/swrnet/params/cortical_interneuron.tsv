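# Fast-spiking cortical interneuron: single-compartment Wang-Buzsaki cell with the
# leak heterogeneity used in the Compte et al. 2003 cortical network.
name	value	units	source
Cm	1.0	uF/cm2	Wang & Buzsaki 1996
area	0.02	mm2	Compte et al. 2003
g_L	0.1025	mS/cm2	Compte et al. 2003
g_L_sd	0.0025	mS/cm2	Compte et al. 2003 (population heterogeneity)
E_L	-63.8	mV	Compte et al. 2003
E_L_sd	0.15	mV	Compte et al. 2003 (population heterogeneity)
g_Na	35.0	mS/cm2	Wang & Buzsaki 1996
E_Na	55.0	mV	Wang & Buzsaki 1996
g_K	9.0	mS/cm2	Wang & Buzsaki 1996
E_K	-90.0	mV	Wang & Buzsaki 1996
phi	5.0	1	Wang & Buzsaki 1996 (temperature factor for h, n)
spike_threshold	10.0	mV	presynaptic spike detection threshold
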