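"""Postsynaptic current generation for all synapse kinds.

Every synapse kind follows the same first-order scheme: a presynaptic spike
instantaneously increments the postsynaptic aggregate gating variable
``s_syn`` by ``multiplicity * alpha_syn * increment_scaling`` (the scaling is
1/3 for cortical excitatory kinds, 1/2 for cortical inhibitory kinds, 1
elsewhere) and ``s_syn`` decays exponentially with ``tau_syn``.  Each cell
carries one aggregate variable per kind, not one per synapse.

The synaptic current is ``I_syn = g_syn * s_syn * (V - V_syn)`` (outward
positive); the cortical NMDA current additionally carries the voltage
dependent magnesium block.  Unitary cortico-hippocampal conductances are
calibrated against the target EPSP/EPSC of the mossy-fiber and
temporoammonic synapses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cells import (CellModelSpec, ConfigurationError, SynapticEvent,
                    simulate_single_cell)

@dataclass(frozen=True)
class SynapseKind:
    name: str
    g_nS: float
    E_mV: float
    tau_ms: float
    alpha: float
    increment_scaling: float
    target: str  # "soma" or "dend"

    @property
    def is_nmda(self) -> bool:
        return "nmda" in self.name


def _load_registry() -> dict[str, SynapseKind]:
    ref = importlib.resources.files("swrnet") / "params" / "synapses.tsv"
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for _, r in tab.iterrows():
        out[r["kind"]] = SynapseKind(
            name=r["kind"], g_nS=float(r["g_nS"]), E_mV=float(r["E_mV"]),
            tau_ms=float(r["tau_ms"]), alpha=float(r["alpha"]),
            increment_scaling=float(r["increment_scaling"]),
            target=str(r["target"]))
    return out


_REGISTRY = _load_registry()


def get_synapse_kind(name: str, **overrides) -> SynapseKind:
    """Look up a synapse kind, optionally overriding parameters."""
    if name not in _REGISTRY:
        raise ConfigurationError(f"unknown synapse kind: {name!r}")
    kind = _REGISTRY[name]
    return replace(kind, **overrides) if overrides else kind


def list_synapse_kinds() -> list[str]:
    return sorted(_REGISTRY)


@dataclass
class SynapticState:
    """Aggregate gating state of one cell: kind name -> s (and x for NMDA)."""

    s: dict[str, float]
    x: dict[str, float]

    @classmethod
    def zeros(cls, kinds) -> "SynapticState":
        return cls(s={k: 0.0 for k in kinds}, x={k: 0.0 for k in kinds})


def apply_presynaptic_spike(state: SynapticState, kind: SynapseKind | str,
                            multiplicity: int = 1) -> SynapticState:
    """Instantaneous increment of s (or of x for NMDA kinds) by one spike."""
    if isinstance(kind, str):
        kind = get_synapse_kind(kind)
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    state.s[kind.name] = state.s.get(kind.name, 0.0) + \
        multiplicity * kind.alpha * kind.increment_scaling
    return state


def synaptic_current(state: SynapticState, kind: SynapseKind | str,
                     V: float) -> float:
    """I_syn = g s (V - E) in nA (positive = outward); NMDA adds Mg block."""
    if isinstance(kind, str):
        kind = get_synapse_kind(kind)
    if not np.isfinite(V):
        raise ValueError("membrane potential must be finite")
    s = state.s.get(kind.name, 0.0)
    block = 1.0 / (1.0 + 0.2801 * np.exp(-0.062 * V)) if kind.is_nmda else 1.0
    return kind.g_nS * s * block * (V - kind.E_mV) * 1e-3


def decay_step(state: SynapticState, kind: SynapseKind | str,
               dt: float) -> SynapticState:
    """Advance the gating variable(s) of one kind by dt with no spikes."""
    if isinstance(kind, str):
        kind = get_synapse_kind(kind)
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if kind.tau_ms <= 0:
        raise ConfigurationError("tau_syn must be positive")
    state.s[kind.name] = state.s.get(kind.name, 0.0) * \
        np.exp(-dt / kind.tau_ms)
    return state


# ---------------------------------------------------------------------------
# unitary-response calibration
# ---------------------------------------------------------------------------

_POSTSYN_MODEL = {
    "MF_to_PY": "ca_pyramidal_pinsky_rinzel",
    "MF_to_IN": "ca_interneuron_wang_buzsaki",
    "TA_to_PY": "ca_pyramidal_pinsky_rinzel",
    "TA_to_IN": "ca_interneuron_wang_buzsaki",
}


def unitary_response(kind_name: str, duration: float = 150.0,
                     dt: float = 0.05, settle: float = 50.0):
    """Peak somatic EPSP (mV) and peak synaptic current (nA) of one unitary
    event of a cortico-hippocampal synapse kind on its resting target cell."""
    kind = get_synapse_kind(kind_name)
    model = _POSTSYN_MODEL.get(kind_name)
    if model is None:
        raise ConfigurationError(
            f"{kind_name!r} has no designated postsynaptic cell class")
    spec = CellModelSpec(model)
    trace = simulate_single_cell(
        spec, [SynapticEvent(time=settle, kind=kind_name)],
        duration=duration, dt=dt, rec_dt=0.2)
    v = trace.values["soma"]
    t = trace.times
    pre = t <= settle
    v_rest = v[pre][-1]
    epsp = float(np.max(v[~pre]) - v_rest)
    # peak current occurs right after the jump, on the target compartment
    v_comp = trace.values.get(kind.target, trace.values["soma"])
    v_at = float(v_comp[pre][-1])
    epsc = abs(kind.g_nS * kind.alpha * kind.increment_scaling
               * (v_at - kind.E_mV)) * 1e-3
    return epsp, epsc
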