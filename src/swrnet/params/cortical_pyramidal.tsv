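# Two-compartment regular-spiking cortical pyramidal cell (Compte et al. 2003 variant).
# Axo-somatic compartment: INa, IK, IA, IKS; dendritic: ICa, IKCa, INaP, IAR, IKNa.
# g_KNa is reduced from the Compte default 1.33 to 0.5 mS/cm2 to lengthen UP states.
# Heterogeneity: gL and EL are drawn per cell (SD columns), as in the source model.
name	value	units	source
Cm	1.0	uF/cm2	Compte et al. 2003
area_soma	0.015	mm2	Compte et al. 2003
area_dend	0.035	mm2	Compte et al. 2003
g_sd	1.75	uS	Compte et al. 2003 (somato-dendritic coupling)
g_sd_sd	0.1	uS	Compte et al. 2003 (population heterogeneity)
g_L	0.0667	mS/cm2	Compte et al. 2003
g_L_sd	0.0067	mS/cm2	Compte et al. 2003 (population heterogeneity)
E_L	-60.95	mV	Compte et al. 2003
E_L_sd	0.3	mV	Compte et al. 2003 (population heterogeneity)
g_Na	50.0	mS/cm2	Compte et al. 2003
E_Na	55.0	mV	Compte et al. 2003
g_K	10.5	mS/cm2	Compte et al. 2003
E_K	-100.0	mV	Compte et al. 2003
g_A	1.0	mS/cm2	Compte et al. 2003
g_KS	0.576	mS/cm2	Compte et al. 2003
g_Ca	0.43	mS/cm2	Compte et al. 2003
E_Ca	120.0	mV	Compte et al. 2003
g_KCa	0.57	mS/cm2	Compte et al. 2003
KD_Ca	30.0	uM	Compte et al. 2003
alpha_Ca	0.005	uM cm2/(ms uA)	Compte et al. 2003
tau_Ca	150.0	ms	Compte et al. 2003
g_NaP	0.0686	mS/cm2	Compte et al. 2003
g_AR	0.0257	mS/cm2	Compte et al. 2003
g_KNa	0.5	mS/cm2	reduced from 1.33 (Compte et al. 2003) to prolong UP states
alpha_Na	0.01	mM cm2/(ms uA)	Compte et al. 2003
R_pump	0.018	mM/ms	Compte et al. 2003
Na_eq	9.5	mM	Compte et al. 2003
Na_half	15.0	mM	Compte et al. 2003 (pump half-activation)
phi	4.0	1	Compte et al. 2003 (temperature factor for h, n)
spike_threshold	10.0	mV	presynaptic spike detection threshold
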