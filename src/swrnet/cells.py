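"""Single-cell conductance-based models for the four cell classes.

Four classes are exposed through :class:`CellModelSpec`:

``cortical_pyramidal_2comp``
    Two-compartment regular-spiking cell (Compte-type) with Na- and
    Ca-dependent K currents supporting slow UP/DOWN alternation.
``cortical_interneuron`` / ``ca_interneuron_wang_buzsaki``
    Single-compartment fast-spiking Wang-Buzsaki cell.
``ca_pyramidal_pinsky_rinzel``
    Two-compartment bursting Pinsky-Rinzel cell (CA3/CA1 pyramidal cells),
    expressed on the physiological voltage scale (original shifted by -60 mV).

Parameters are vendored in ``params/*.tsv`` with per-value provenance and can
be overridden per spec.  Integration is fixed-step RK2 (dt = 0.05 ms in
production; finer steps are available for convergence/oracle tests).  The
single-cell simulator integrates frame by frame (one recording interval per
kernel call), so membrane *and* gating trajectories are sampled exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import run_ca, run_cortex

MODEL_KINDS = (
    "cortical_pyramidal_2comp",
    "cortical_interneuron",
    "ca_pyramidal_pinsky_rinzel",
    "ca_interneuron_wang_buzsaki",
)

_PARAM_FILES = {
    "cortical_pyramidal_2comp": "cortical_pyramidal.tsv",
    "cortical_interneuron": "cortical_interneuron.tsv",
    "ca_pyramidal_pinsky_rinzel": "ca_pyramidal.tsv",
    "ca_interneuron_wang_buzsaki": "ca_interneuron.tsv",
}

SPIKE_THRESHOLD = _kernels.SPIKE_THRESHOLD

_MM2_TO_CM2 = 1e-2

_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_F = np.zeros(0, dtype=np.float64)


def csr_empty(n_src: int):
    """CSR triple for a projection with no edges."""
    return np.zeros(n_src + 1, dtype=np.int64), _EMPTY_I, _EMPTY_F


class ConfigurationError(ValueError):
    """Raised for unknown model kinds or inconsistent parameters."""


class NumericalInstabilityError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


def load_cell_params(model_kind: str) -> dict[str, float]:
    """Load the vendored parameter table for a cell class as a name->value dict."""
    if model_kind not in _PARAM_FILES:
        raise ConfigurationError(f"unknown model_kind: {model_kind!r}")
    ref = importlib.resources.files("swrnet") / "params" / _PARAM_FILES[model_kind]
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(tab["name"], tab["value"].astype(float)))


@dataclass
class CellModelSpec:
    """A cell class plus named parameter overrides (conductances mS/cm2, mV)."""

    model_kind: str
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    spike_threshold: float = SPIKE_THRESHOLD

    def params(self) -> dict[str, float]:
        p = load_cell_params(self.model_kind)
        for k, v in self.parameter_overrides.items():
            if k not in p:
                raise ConfigurationError(
                    f"unknown parameter {k!r} for {self.model_kind}")
            p[k] = float(v)
        return p


@dataclass
class VoltageTrace:
    """Sampled membrane potentials plus threshold-crossing spike times."""

    times: np.ndarray                 # ms
    values: dict[str, np.ndarray]     # compartment name -> mV
    spike_times: np.ndarray           # ms
    gating: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, v in self.values.items():
            rows.append(pd.DataFrame(
                {"time_ms": self.times, "compartment": comp, "V_mV": v}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class CurrentStep:
    """Constant current injection (uA/cm2 into the cell's input compartment:
    the dendrite for two-compartment cells) over [start, stop) ms."""

    start: float
    stop: float
    amplitude: float


@dataclass
class SynapticEvent:
    """A presynaptic spike arriving at ``time`` ms on a synapse of ``kind``."""

    time: float
    kind: str
    multiplicity: int = 1


# ---------------------------------------------------------------------------
# parameter vector assembly (kernel layouts)
# ---------------------------------------------------------------------------


def compte_py_vector(p: dict[str, float]) -> np.ndarray:
    return np.array([
        p["g_Na"], p["E_Na"], p["g_K"], p["E_K"], p["g_A"], p["g_KS"],
        p["g_Ca"], p["E_Ca"], p["g_KCa"], p["KD_Ca"], p["alpha_Ca"],
        p["tau_Ca"], p["g_NaP"], p["g_AR"], p["g_KNa"], p["alpha_Na"],
        p["R_pump"], p["Na_eq"], p["Na_half"], p["phi"], p["Cm"],
        p["area_soma"] / p["area_dend"],
    ])


def wb_vector(p: dict[str, float]) -> np.ndarray:
    return np.array([p["g_Na"], p["E_Na"], p["g_K"], p["E_K"], p["phi"],
                     p["Cm"]])


def pr_vector(p: dict[str, float]) -> np.ndarray:
    return np.array([
        p["g_Na"], p["E_Na"], p["g_KDR"], p["E_K"], p["g_Ca"], p["E_Ca"],
        p["g_KC"], p["g_KAHP"], p["g_L"], p["E_L"], p["g_c"], p["p_soma"],
        p["Cm"],
    ])


# ---------------------------------------------------------------------------
# gating steady states (initial conditions)
# ---------------------------------------------------------------------------


def _ss_compte(v):
    v = np.asarray(v, dtype=float)
    ah = 0.07 * np.exp(-(v + 50.0) / 10.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 20.0) / 10.0))
    an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 25.0)
    return {
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "hA": 1.0 / (1.0 + np.exp((v + 80.0) / 6.0)),
        "mKS": 1.0 / (1.0 + np.exp(-(v + 34.0) / 6.5)),
    }


def _ss_wb(v):
    v = np.asarray(v, dtype=float)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return {"h": ah / (ah + bh), "n": an / (an + bn)}


def _ss_pr(v):
    v = np.asarray(v, dtype=float)
    u = v + 60.0
    ah = 0.128 * np.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    an = 0.016 * (35.1 - u) / (np.exp((35.1 - u) / 5.0) - 1.0)
    bn = 0.25 * np.exp(0.5 - 0.025 * u)
    as_ = 1.6 / (1.0 + np.exp(-0.072 * (u - 65.0)))
    bs = 0.02 * (u - 51.1) / (np.exp((u - 51.1) / 5.0) - 1.0)
    ac = np.exp((u - 10.0) / 11.0 - (u - 6.5) / 27.0) / 18.975
    bc = 2.0 * np.exp((6.5 - u) / 27.0) - ac
    return {
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "s": as_ / (as_ + bs),
        "c": ac / (ac + bc),
        "q": np.zeros_like(u),
    }


def _check_finite(arrays: dict[str, np.ndarray]):
    for name, a in arrays.items():
        if not np.all(np.isfinite(a)):
            raise NumericalInstabilityError(
                f"state variable {name!r} became non-finite during integration")


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------


def simulate_single_cell(spec: CellModelSpec, input_protocol=(),
                         duration: float = 500.0, dt: float = 0.05,
                         rec_dt: float = 1.0, seed: int = 0,
                         initial_v: float | None = None,
                         noise_sigma: float = 0.0) -> VoltageTrace:
    """Integrate one cell under a protocol of current steps and synaptic events.

    Current-step edges are resolved on the recording grid (``rec_dt``);
    synaptic events on the integration grid (``dt``).  Gaussian current noise
    of standard deviation ``noise_sigma`` (uA/cm2 at 1 ms) can be added to the
    input compartment.  Returns a :class:`VoltageTrace` sampled every
    ``rec_dt`` ms including gating-variable traces.
    """
    from .synapses import get_synapse_kind  # deferred import (cycle)

    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if duration < dt:
        raise ConfigurationError("duration must be at least dt")
    if spec.model_kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model_kind: {spec.model_kind!r}")

    steps = [e for e in input_protocol if isinstance(e, CurrentStep)]
    syn_events = sorted(
        (e for e in input_protocol if isinstance(e, SynapticEvent)),
        key=lambda e: e.time)
    for e in syn_events:
        if not 0.0 <= e.time <= duration:
            raise ConfigurationError(
                "protocol events must lie within [0, duration]")
        if e.multiplicity < 1:
            raise ConfigurationError("synaptic event multiplicity must be >= 1")
    kind_names = []
    for e in syn_events:
        if e.kind not in kind_names:
            kind_names.append(e.kind)
    if len(kind_names) > 2:
        raise ConfigurationError(
            "at most two distinct synapse kinds per single-cell protocol")
    kinds = [get_synapse_kind(k) for k in kind_names]

    rec_stride = max(1, int(round(rec_dt / dt)))
    n_frames = int(round(duration / (rec_stride * dt)))
    times = np.arange(n_frames + 1) * rec_stride * dt
    rng = np.random.default_rng(seed)

    def current_at(t0):
        return sum(st.amplitude for st in steps if st.start <= t0 < st.stop)

    # events per (channel, global step)
    n_steps_total = n_frames * rec_stride
    ev = {0: {}, 1: {}}
    for e in syn_events:
        chan = kind_names.index(e.kind)
        k = kinds[chan]
        st = min(int(round(e.time / dt)), n_steps_total - 1)
        ev[chan][st] = ev[chan].get(st, 0.0) + \
            e.multiplicity * k.alpha * k.increment_scaling

    cell = _SingleCell(spec, kinds, initial_v)
    out = {nm: np.zeros(n_frames + 1) for nm in cell.trace_names}
    gat = {nm: np.zeros(n_frames + 1) for nm in cell.gating_names}
    snap = cell.snapshot()
    for nm in out:
        out[nm][0] = snap[nm]
    for nm in gat:
        gat[nm][0] = snap[nm]
    spike_steps: list[int] = []
    for fr in range(n_frames):
        b0 = fr * rec_stride
        amp = current_at(b0 * dt)
        seg_ev = {chan: [(s - b0, w) for s, w in ev[chan].items()
                         if b0 <= s < b0 + rec_stride] for chan in ev}
        ss = cell.advance(dt, rec_stride, amp, noise_sigma, seg_ev,
                          int(rng.integers(0, 2**31 - 1)))
        spike_steps.extend(b0 + s for s in ss)
        snap = cell.snapshot()
        cell.check_finite()
        for nm in out:
            out[nm][fr + 1] = snap[nm]
        for nm in gat:
            gat[nm][fr + 1] = snap[nm]
    spike_times = np.array(spike_steps, dtype=float) * dt
    values = {nm: out[nm] for nm in cell.trace_names}
    return VoltageTrace(times=times, values=values, spike_times=spike_times,
                        gating=gat)


class _SingleCell:
    """State holder driving the network kernels with a single cell."""

    def __init__(self, spec: CellModelSpec, kinds, initial_v):
        self.kind = spec.model_kind
        p = spec.params()
        self.p = p
        self.syn_kinds = kinds
        if self.kind == "cortical_pyramidal_2comp":
            v0 = p["E_L"] if initial_v is None else float(initial_v)
            ss = _ss_compte([v0])
            self.Vs = np.array([v0]); self.Vd = np.array([v0])
            self.h = ss["h"].copy(); self.n = ss["n"].copy()
            self.hA = ss["hA"].copy(); self.mKS = ss["mKS"].copy()
            # post-activity adapted state: elevated Na pool keeps the cell at rest
            self.Ca = np.array([1e-4]); self.Na = np.array([12.5])
            self.s = np.zeros(4)  # ampa, nmda, x_nmda, gaba
            self.P_py = compte_py_vector(p)
            self.P_in = wb_vector(load_cell_params("cortical_interneuron"))
            self.area_in = p["area_dend"] * _MM2_TO_CM2
            self.trace_names = ("soma", "dend")
            self.gating_names = ("h", "n", "hA", "mKS", "Ca", "Na")
            if len(kinds) > 1:
                raise ConfigurationError(
                    "cortical single-cell protocols support one synapse kind")
        elif self.kind == "ca_pyramidal_pinsky_rinzel":
            v0 = p["E_L"] if initial_v is None else float(initial_v)
            ss = _ss_pr([v0])
            self.Vs = np.array([v0]); self.Vd = np.array([v0])
            self.h = ss["h"].copy(); self.n = ss["n"].copy()
            self.sCa = ss["s"].copy(); self.c = ss["c"].copy()
            # post-burst adapted state: AHP gate q holds the cell at rest
            self.q = np.array([0.15]); self.Ca = np.array([0.2])
            self.P_pr = pr_vector(p)
            self.P_in = wb_vector(load_cell_params("ca_interneuron_wang_buzsaki"))
            self.area_in = 0.5 * p["area_total"] * _MM2_TO_CM2
            self.S_py = np.zeros((4, 1)); self.S_in = np.zeros((4, 0))
            self.trace_names = ("soma", "dend")
            self.gating_names = ("h", "n", "s", "c", "q", "Ca")
        else:  # Wang-Buzsaki interneuron variants
            v0 = p["E_L"] if initial_v is None else float(initial_v)
            ss = _ss_wb([v0])
            self.Vi = np.array([v0])
            self.hi = ss["h"].copy(); self.ni = ss["n"].copy()
            self.P_pr = pr_vector(load_cell_params("ca_pyramidal_pinsky_rinzel"))
            self.P_in = wb_vector(p)
            self.area_in = p["area"] * _MM2_TO_CM2
            self.S_py = np.zeros((4, 0)); self.S_in = np.zeros((4, 1))
            self.trace_names = ("soma",)
            self.gating_names = ("h", "n")
        self._cap = 64
        self._sp = np.zeros(self._cap, dtype=np.int64)
        self._si = np.zeros(self._cap, dtype=np.int64)

    # -- channel tables for the CA kernel (channels 2, 3 host protocol kinds)
    def _chan_tables(self):
        g_py = np.zeros(4); E_py = np.zeros(4); tau_py = np.ones(4)
        comp_py = np.zeros(4, dtype=np.int64)
        g_in = np.zeros(4); E_in = np.zeros(4); tau_in = np.ones(4)
        for off, k in enumerate(self.syn_kinds):
            chan = 2 + off
            gdens = k.g_nS * 1e-6 / self.area_in
            if self.kind == "ca_pyramidal_pinsky_rinzel":
                g_py[chan] = gdens
                E_py[chan] = k.E_mV
                tau_py[chan] = k.tau_ms
                comp_py[chan] = 1 if k.target == "dend" else 0
            else:
                g_in[chan] = gdens
                E_in[chan] = k.E_mV
                tau_in[chan] = k.tau_ms
        return g_py, E_py, tau_py, comp_py, g_in, E_in, tau_in

    def snapshot(self) -> dict[str, float]:
        if self.kind == "cortical_pyramidal_2comp":
            return {"soma": self.Vs[0], "dend": self.Vd[0], "h": self.h[0],
                    "n": self.n[0], "hA": self.hA[0], "mKS": self.mKS[0],
                    "Ca": self.Ca[0], "Na": self.Na[0]}
        if self.kind == "ca_pyramidal_pinsky_rinzel":
            return {"soma": self.Vs[0], "dend": self.Vd[0], "h": self.h[0],
                    "n": self.n[0], "s": self.sCa[0], "c": self.c[0],
                    "q": self.q[0], "Ca": self.Ca[0]}
        return {"soma": self.Vi[0], "h": self.hi[0], "n": self.ni[0]}

    def check_finite(self):
        _check_finite({nm: np.array([v]) for nm, v in self.snapshot().items()})

    def advance(self, dt, nst, amp, sigma, seg_ev, seed) -> list[int]:
        no_rec = np.int64(nst + 1)
        if self.kind == "cortical_pyramidal_2comp":
            evs = sorted(seg_ev.get(0, []))
            ext_steps = np.array([s for s, _ in evs], dtype=np.int64)
            ext_tgt = np.zeros(len(evs), dtype=np.int64)
            ext_w = np.array([w for _, w in evs], dtype=np.float64)
            g_ext = (self.syn_kinds[0].g_nS * 1e-6 / self.area_in
                     if self.syn_kinds else 0.0)
            p = self.p
            cpy, _ = run_cortex(
                dt, nst, no_rec, self.P_py, self.P_in,
                np.array([p["g_L"]]), np.array([p["E_L"]]),
                np.array([p["g_sd"] * 1e-3 / (p["area_soma"] * _MM2_TO_CM2)]),
                np.array([p["g_sd"] * 1e-3 / (p["area_dend"] * _MM2_TO_CM2)]),
                np.zeros(0), np.zeros(0),
                g_ext, 0.0, 0.0, 0.0, 0.0, 0.0,
                0.0, -75.0, 2.0, 10.0, 100.0, 1.0,
                *csr_empty(1), *csr_empty(1), *csr_empty(0), *csr_empty(0),
                ext_steps, ext_tgt, ext_w,
                np.array([amp]), np.array([sigma]), np.zeros(0), np.zeros(0),
                seed,
                self.Vs, self.Vd, self.h, self.n, self.hA, self.mKS,
                self.Ca, self.Na,
                np.zeros(0), np.zeros(0), np.zeros(0),
                self.s[0:1], self.s[1:2], self.s[2:3], self.s[3:4],
                np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0),
                self._sp, self._si,
                np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(1), np.zeros((1, 1)), np.zeros(0, dtype=np.int64))
            return list(self._sp[:cpy])
        g_py, E_py, tau_py, comp_py, g_in, E_in, tau_in = self._chan_tables()
        is_pr = self.kind == "ca_pyramidal_pinsky_rinzel"
        streams = []
        for chan_off in (0, 1):
            evs = sorted(seg_ev.get(chan_off, []))
            streams.append((
                np.array([s for s, _ in evs], dtype=np.int64),
                np.zeros(len(evs), dtype=np.int64),
                np.array([w for _, w in evs], dtype=np.float64)))
        one = (np.array([0, 1], dtype=np.int64), np.zeros(1, dtype=np.int64),
               np.ones(1))
        n_py = 1 if is_pr else 0
        n_in = 0 if is_pr else 1
        e1p = one if is_pr else csr_empty(1)
        e1i = csr_empty(1) if is_pr else one
        sp2 = np.zeros(self._cap, dtype=np.int64)
        si2 = np.zeros(self._cap, dtype=np.int64)
        if is_pr:
            args_state = (self.Vs, self.Vd, self.h, self.n, self.sCa, self.c,
                          self.q, self.Ca, np.zeros(0), np.zeros(0), np.zeros(0))
            gL_in = np.zeros(0); EL_in = np.zeros(0)
        else:
            args_state = (np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0),
                          np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0),
                          self.Vi, self.hi, self.ni)
            gL_in = np.array([self.p["g_L"]]); EL_in = np.array([self.p["E_L"]])
        cpy, cin = run_ca(
            dt, nst, no_rec, self.P_pr, self.P_in, gL_in, EL_in,
            g_py, E_py, tau_py, comp_py, g_in, E_in, tau_in,
            *csr_empty(n_py), *csr_empty(n_py),
            *csr_empty(n_in), *csr_empty(n_in),
            streams[0][0], streams[0][1], streams[0][2], *e1p, *e1i,
            streams[1][0], streams[1][1], streams[1][2], *e1p, *e1i,
            np.full(n_py, amp), np.full(n_py, sigma),
            np.full(n_in, amp), np.full(n_in, sigma),
            seed,
            *args_state,
            self.S_py, self.S_in,
            self._sp, self._si, sp2, si2,
            np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
            np.zeros(4), np.zeros(4),
            np.zeros(1), np.zeros(1), np.zeros((1, 1, 4)),
            np.zeros((1, max(n_py, 1))),
            np.zeros(0, dtype=np.int64))
        if is_pr:
            return list(self._sp[:cpy])
        return list(sp2[:cin])


# ---------------------------------------------------------------------------
# spike detection on sampled traces
# ---------------------------------------------------------------------------


def detect_spikes(values: np.ndarray, times: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD) -> np.ndarray:
    """Times of upward threshold crossings of a sampled somatic trace.

    A crossing is counted once (one-sample hold-off): the sample must come
    from below threshold.  An empty trace yields an empty result; NaN samples
    raise a ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size == 0:
        return np.zeros(0)
    if np.any(np.isnan(values)):
        raise ValueError("trace contains NaN samples")
    below = values[:-1] < threshold
    above = values[1:] >= threshold
    idx = np.nonzero(below & above)[0] + 1
    return times[idx]
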