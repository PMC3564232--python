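# swrnet

A coupled cortical–CA3–CA1 spiking-network model of how the neocortical slow
oscillation (SO) entrains hippocampal activity and sharp wave-ripples
(SWRs), together with the full detection and analysis stack: UP-state / SO
cycle / CA3-burst / ripple detection, SO-aligned z-scored firing, spike–
ripple phase locking, and a classification pipeline for sleep spike-train
recordings (UP/DOWN-cells, UP/DOWN-ripples, four response groups).

**Who it is for.** Computational neuroscientists studying cortico-
hippocampal coupling during slow-wave sleep: how the <1 Hz UP/DOWN
alternation of the neocortex, fed into the hippocampus through the
dentate/mossy-fiber route (CA3) and the temporoammonic route (CA1), shapes
when CA3 population bursts and CA1 ripples occur and which CA1 cells fire
in them.

## The model

Three 1-D networks of Hodgkin–Huxley-type cells integrated with fixed-step
RK2 at dt = 0.05 ms:

* **Cortex** (1000 two-compartment pyramidal cells + 250 fast-spiking
  interneurons) self-generates the slow oscillation: recurrent AMPA/NMDA
  excitation ignites UP states, GABA_A inhibition balances them, and a
  Na-dependent K current (g_KNa = 0.5 mS/cm²) terminates them.
* **CA3** (1000 Pinsky–Rinzel pyramidal cells + 100 Wang–Buzsáki
  interneurons, recurrent excitation, no IN–IN coupling) produces
  quasi-synchronized population bursts under a noisy depolarizing drive.
  Each cortical cell contacts k_DG−PY pyramidal cells and k_DG−IN
  interneurons uniformly (the mossy-fiber route; unitary EPSP 5 mV on
  pyramidal cells, α_syn = 70).
* **CA1** (same sizes, dense recurrent inhibition, no PY–PY coupling)
  receives CA3 Schaffer collaterals — 130 per CA3 cell, with
  synapses-per-connection drawn per target from |N(13, 13)| (baseline) or
  |N(20, 20)| (increased drive); cells above 1.5 × mean form the
  "strongly-driven subset" — and direct temporoammonic input (k_EC−PY = 200,
  k_EC−IN = 2 in the full model; unitary EPSPs 0.16 / 1 mV).  Ripples are
  detected from the 150–200 Hz band of the summed synaptic conductance of a
  560 µm "recording site" (50 PY, 6 IN).

All synapses use one aggregate gating variable per (cell, kind):
`I_syn = g_syn · s_syn · (V − V_syn)`, s incremented by
`multiplicity × α_syn × scaling` per presynaptic spike (+10 mV threshold)
and decaying exponentially.  Scenarios add the projections progressively
(`cortex_only`, `cortex_to_CA3` with k_DG−IN ∈ {0, 1, 10},
`cortex_CA3_CA1_no_TA`, `TA_only_no_Schaffer`, `full_model`); because the
coupling is feedforward the engine integrates stage-wise and can reuse a
cortical run across downstream variants.  See `docs/methods.md` for the
full model account, calibration, and limitations.

## Worked example

```python
from swrnet import ScenarioConfig, run_scenario
from swrnet.events import detect_up_states, extract_so_cycles, so_frequency

cfg = ScenarioConfig(scenario="cortex_only", duration_s=10.0, seed=1)
res = run_scenario(cfg)
lfp = res.signals["ctx_act"]            # total synaptic activity, 1 kHz
ups = detect_up_states(lfp)             # 0.45 x SD threshold, 100 ms merge
cycles = extract_so_cycles(ups, lfp)
py = res.spikes[res.spikes.population == "ctx_py"].time_ms.to_numpy()
rate = ups.contains(py).sum() / 1000 / (ups.durations.sum() * 1e-3)
print(f"{len(ups)} UP states, SO {so_frequency(cycles):.2f} Hz, "
      f"UP-state PY rate {rate:.1f} Hz")
```

prints (seed 1):

```
9 UP states, SO 0.84 Hz, UP-state PY rate 15.2 Hz
```

i.e. the isolated cortex alternates between silent DOWN states and active
UP states at 0.84 Hz — the slow-oscillation regime — with pyramidal cells
firing ~15 Hz inside UP states.  The same run can drive the hippocampal
stages (`scenario="cortex_to_CA3"` etc.), and `swrnet.sleep` classifies
spike tables from any source:

```bash
swrnet simulate --scenario full_model --duration 10 --seed 1 --out run1/
swrnet detect --run run1/ --out run1/events/
swrnet synth --duration 600 --seed 0 --out synth/
swrnet classify --data synth/ --out synth/cls/
```

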