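"""Scenario assembly and integration of the coupled cortico-hippocampal model.

The inter-network projections (mossy fibers cortex->CA3, Schaffer collaterals
CA3->CA1, temporoammonic cortex->CA1) are strictly feedforward, so a scenario
is integrated stage-wise: the cortical network first, then CA3 driven by the
recorded cortical spike train, then CA1 driven by the recorded CA3 and
cortical spike trains.  This is mathematically identical to integrating the
coupled system and lets a single cortical run be reused across variants of
the downstream wiring.

Spikes are recorded at every time step (dt = 0.05 ms); all signals are
sampled every 1 ms:

``ctx_act``
    Total cortical synaptic activity: postsynaptic current magnitudes of all
    connection types summed over the whole cortical network (UP states are
    detected from this signal).
``ca1_site_g``
    Total synaptic conductance summed over all connections onto the CA1
    recording site (50 pyramidal cells, 6 interneurons), Schaffer synapses
    excluded -- the pyramidal-layer LFP proxy used for ripple detection.
``ca1_site_vin``
    Mean membrane potential of the recording-site interneurons (ripple-band
    spectral analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._kernels import run_ca, run_cortex
from .cells import (ConfigurationError, _ss_compte, _ss_pr, _ss_wb,
                    compte_py_vector, csr_empty, load_cell_params, pr_vector,
                    wb_vector)
from .connectome import (BASELINE_SCHAFFER, DEFAULT_LAYOUT, INCREASED_SCHAFFER,
                         ConnectionTable, NetworkLayout,
                         assign_schaffer_multiplicities,
                         build_gaussian_footprint, build_schaffer_projection,
                         build_uniform_projection)
from .synapses import get_synapse_kind

_MM2_TO_CM2 = 1e-2

SCENARIOS = ("cortex_only", "cortex_to_CA3", "cortex_CA3_CA1_no_TA",
             "TA_only_no_Schaffer", "full_model", "ca3_only")

#: Gaussian footprint SDs (um).  The cortical values follow the source
#: cortical model (excitatory axons twice as wide as inhibitory); hippocampal
#: values are this package's calibration reproducing the stated pairwise
#: connectivity probabilities (see docs/methods.md).
FOOTPRINTS = {
    "ctx_exc": 250.0,
    "ctx_inh": 125.0,
    "ca3_pp": 8000.0,
    "ca3_pi": 2000.0,
    "ca3_ip": 300.0,
    "ca1_pi": 2400.0,
    "ca1_ip": 300.0,
    "ca1_ii": 300.0,
    "schaffer": 1900.0,
}

#: per-source connection counts
K_COUNTS = {
    "ctx": 20,       # each cortical cell onto each target type
    "ca3_pp": 55,
    "ca3_pi": 5,
    "ca3_ip": 68,
    "ca1_pi": 20,
    "ca1_ip": 400,
    "ca1_ii": 100,
    "schaffer": 130,
}

#: background drive (mean uA/cm2, SD uA/cm2 at 1 ms) per population; the CA3
#: noisy depolarizing drive stays on in coupled runs (spontaneous DOWN-state
#: bursts depend on it), the cortical noise seeds UP-state initiation.
NOISE = {
    "ctx_py": (0.0, 0.25),
    "ctx_in": (0.0, 0.0),
    "ca3_py": (0.2, 1.2),
    "ca3_in": (0.0, 0.0),
    "ca1_py": (0.0, 1.3),
    "ca1_in": (0.0, 0.0),
}


@dataclass
class ScenarioConfig:
    """Which projections exist, their strengths, and run length/seed."""

    scenario: str = "full_model"
    duration_s: float = 10.0
    seed: int = 1
    dt_ms: float = 0.05
    k_dg_py: int = 1
    k_dg_in: int = 1
    k_ec_py: int = 200
    k_ec_in: int = 2
    schaffer: str = "increased"         # "baseline" or "increased"
    noise: dict = field(default_factory=lambda: dict(NOISE))
    footprints: dict = field(default_factory=lambda: dict(FOOTPRINTS))
    k_counts: dict = field(default_factory=lambda: dict(K_COUNTS))

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.schaffer not in ("baseline", "increased"):
            raise ConfigurationError("schaffer must be baseline or increased")
        for k in ("k_dg_py", "k_dg_in", "k_ec_py", "k_ec_in"):
            if getattr(self, k) < 0:
                raise ConfigurationError(f"{k} must be >= 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")

    @property
    def schaffer_rule(self):
        return BASELINE_SCHAFFER if self.schaffer == "baseline" \
            else INCREASED_SCHAFFER

    def wants_ca3(self) -> bool:
        return self.scenario in ("cortex_to_CA3", "cortex_CA3_CA1_no_TA",
                                 "full_model", "ca3_only")

    def wants_ca1(self) -> bool:
        return self.scenario in ("cortex_CA3_CA1_no_TA", "TA_only_no_Schaffer",
                                 "full_model")

    def wants_cortex(self) -> bool:
        return self.scenario != "ca3_only"

    def wants_schaffer(self) -> bool:
        return self.scenario in ("cortex_CA3_CA1_no_TA", "full_model")

    def wants_ta(self) -> bool:
        return self.scenario in ("TA_only_no_Schaffer", "full_model")


@dataclass
class SimulationResult:
    """Spike events plus 1 kHz signal traces of one scenario run."""

    spikes: pd.DataFrame          # time_ms, population, cell_index
    signals: dict                 # name -> 1 kHz np.ndarray
    duration_ms: float
    n_cells: dict                 # population -> size
    config: ScenarioConfig
    schaffer_cells: pd.DataFrame | None = None
    site_py: np.ndarray | None = None
    site_in: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def spike_times(self, population: str) -> pd.DataFrame:
        return self.spikes[self.spikes["population"] == population]

    def save(self, outdir):
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False)
        sig = pd.DataFrame({"time_ms": np.arange(1, 1 + len(
            next(iter(self.signals.values()))))})
        for k, v in self.signals.items():
            sig[k] = v
        sig.to_csv(out / "signals.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        with open(out / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=2)
        if self.schaffer_cells is not None:
            self.schaffer_cells.to_csv(out / "schaffer_cells.tsv", sep="\t",
                                       index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _weights(table: ConnectionTable, kind_name: str) -> np.ndarray:
    k = get_synapse_kind(kind_name)
    return table.edges["multiplicity"].to_numpy(float) * k.alpha \
        * k.increment_scaling


def _density(g_nS: float, area_cm2: float) -> float:
    return g_nS * 1e-6 / area_cm2


def _spike_arrays(steps, idx, count, population, dt):
    return pd.DataFrame({
        "time_ms": (steps[:count] + 1) * dt,
        "population": population,
        "cell_index": idx[:count].astype(np.int64),
    })


class _StreamPair:
    """Step-sorted external spike stream feeding a CA-network kernel."""

    def __init__(self, steps=None, src=None):
        self.steps = np.zeros(0, dtype=np.int64) if steps is None else steps
        self.src = np.zeros(0, dtype=np.int64) if src is None else src
        self.w = np.ones(self.steps.shape[0])


# ---------------------------------------------------------------------------
# cortical stage
# ---------------------------------------------------------------------------


def build_cortex_wiring(cfg: ScenarioConfig, rng: np.random.Generator,
                        layout: NetworkLayout = DEFAULT_LAYOUT):
    k = cfg.k_counts["ctx"]
    fp = cfg.footprints
    # cortical convention: every cell receives exactly k connections of each
    # type (source-model wiring), targets chosen by the Gaussian footprint
    t_pp = build_gaussian_footprint(layout.cortex_py, layout.cortex_py, k,
                                    fp["ctx_exc"], rng, "ctx_ampa_pp",
                                    fixed="in")
    t_pi = build_gaussian_footprint(layout.cortex_py, layout.cortex_in, k,
                                    fp["ctx_exc"], rng, "ctx_ampa_pi",
                                    fixed="in")
    t_ip = build_gaussian_footprint(layout.cortex_in, layout.cortex_py, k,
                                    fp["ctx_inh"], rng, "ctx_gaba_ip",
                                    fixed="in")
    t_ii = build_gaussian_footprint(layout.cortex_in, layout.cortex_in, k,
                                    fp["ctx_inh"], rng, "ctx_gaba_ii",
                                    fixed="in")
    return {"pp": t_pp, "pi": t_pi, "ip": t_ip, "ii": t_ii}


def run_cortex_stage(cfg: ScenarioConfig, wiring, ss: np.random.SeedSequence,
                     layout: NetworkLayout = DEFAULT_LAYOUT):
    p = load_cell_params("cortical_pyramidal_2comp")
    pi = load_cell_params("cortical_interneuron")
    n_py = layout.cortex_py.n
    n_in = layout.cortex_in.n
    dt = cfg.dt_ms
    n_steps = int(round(cfg.duration_s * 1000.0 / dt))
    rec_stride = int(round(1.0 / dt))
    rng = np.random.default_rng(ss.spawn(1)[0])

    # heterogeneous passive parameters (source-model convention)
    gL_py = rng.normal(p["g_L"], p["g_L_sd"], n_py)
    EL_py = rng.normal(p["E_L"], p["E_L_sd"], n_py)
    gsd = rng.normal(p["g_sd"], p["g_sd_sd"], n_py)
    gL_in = rng.normal(pi["g_L"], pi["g_L_sd"], n_in)
    EL_in = rng.normal(pi["E_L"], pi["E_L_sd"], n_in)

    area_s = p["area_soma"] * _MM2_TO_CM2
    area_d = p["area_dend"] * _MM2_TO_CM2
    area_i = pi["area"] * _MM2_TO_CM2
    gsd_s = gsd * 1e-3 / area_s
    gsd_d = gsd * 1e-3 / area_d

    v0 = rng.uniform(-70.0, -60.0, n_py)
    sspy = _ss_compte(v0)
    Vs = v0.copy(); Vd = v0.copy()
    h = sspy["h"]; n_ = sspy["n"]; hA = sspy["hA"]; mKS = sspy["mKS"]
    Ca = np.full(n_py, 1e-4)
    Na = np.full(n_py, 12.5)   # post-activity adapted start (DOWN-like)
    vi0 = rng.uniform(-70.0, -60.0, n_in)
    ssin = _ss_wb(vi0)
    Vi = vi0.copy(); hi = ssin["h"]; ni = ssin["n"]

    kinds = {nm: get_synapse_kind(nm) for nm in
             ("ctx_ampa_pp", "ctx_nmda_pp", "ctx_ampa_pi", "ctx_nmda_pi",
              "ctx_gaba_ip", "ctx_gaba_ii")}
    cap_py = int(n_py * cfg.duration_s * 120) + 1000
    cap_in = int(n_in * cfg.duration_s * 250) + 1000
    spk_ps = np.zeros(cap_py, dtype=np.int64)
    spk_pi = np.zeros(cap_py, dtype=np.int64)
    spk_is = np.zeros(cap_in, dtype=np.int64)
    spk_ii = np.zeros(cap_in, dtype=np.int64)
    n_frames = n_steps // rec_stride
    lfp = np.zeros(n_frames)
    v_rec = np.zeros((n_frames, 0))
    noise = cfg.noise
    c_py, c_in = run_cortex(
        dt, n_steps, rec_stride,
        compte_py_vector(p), wb_vector(pi),
        gL_py, EL_py, gsd_s, gsd_d, gL_in, EL_in,
        _density(kinds["ctx_ampa_pp"].g_nS, area_d),
        _density(kinds["ctx_nmda_pp"].g_nS, area_d),
        _density(kinds["ctx_gaba_ip"].g_nS, area_s),
        _density(kinds["ctx_ampa_pi"].g_nS, area_i),
        _density(kinds["ctx_nmda_pi"].g_nS, area_i),
        _density(kinds["ctx_gaba_ii"].g_nS, area_i),
        0.0, kinds["ctx_gaba_ip"].E_mV,
        kinds["ctx_ampa_pp"].tau_ms, kinds["ctx_gaba_ip"].tau_ms,
        kinds["ctx_nmda_pp"].tau_ms,
        kinds["ctx_nmda_pp"].alpha / kinds["ctx_ampa_pp"].alpha,
        *wiring["pp"].to_csr(n_py, _weights(wiring["pp"], "ctx_ampa_pp")),
        *wiring["pi"].to_csr(n_py, _weights(wiring["pi"], "ctx_ampa_pi")),
        *wiring["ip"].to_csr(n_in, _weights(wiring["ip"], "ctx_gaba_ip")),
        *wiring["ii"].to_csr(n_in, _weights(wiring["ii"], "ctx_gaba_ii")),
        np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
        np.zeros(0),
        np.full(n_py, noise["ctx_py"][0]), np.full(n_py, noise["ctx_py"][1]),
        np.full(n_in, noise["ctx_in"][0]), np.full(n_in, noise["ctx_in"][1]),
        _kernel_seed(ss.spawn(1)[0]),
        Vs, Vd, h, n_, hA, mKS, Ca, Na, Vi, hi, ni,
        np.zeros(n_py), np.zeros(n_py), np.zeros(n_py), np.zeros(n_py),
        np.zeros(n_in), np.zeros(n_in), np.zeros(n_in), np.zeros(n_in),
        spk_ps, spk_pi, spk_is, spk_ii,
        lfp, v_rec, np.zeros(0, dtype=np.int64))
    if c_py >= cap_py or c_in >= cap_in:
        raise RuntimeError("cortical spike buffer saturated; raise the cap")
    return {
        "py_steps": spk_ps[:c_py].copy(), "py_idx": spk_pi[:c_py].copy(),
        "in_steps": spk_is[:c_in].copy(), "in_idx": spk_ii[:c_in].copy(),
        "lfp": lfp,
    }


# ---------------------------------------------------------------------------
# CA stages
# ---------------------------------------------------------------------------


def build_ca3_wiring(cfg: ScenarioConfig, rng: np.random.Generator,
                     layout: NetworkLayout = DEFAULT_LAYOUT):
    fp = cfg.footprints
    kc = cfg.k_counts
    t_pp = build_gaussian_footprint(layout.ca3_py, layout.ca3_py, kc["ca3_pp"],
                                    fp["ca3_pp"], rng, "ca3_ampa_pp")
    t_pi = build_gaussian_footprint(layout.ca3_py, layout.ca3_in, kc["ca3_pi"],
                                    fp["ca3_pi"], rng, "ca3_ampa_pi")
    t_ip = build_gaussian_footprint(layout.ca3_in, layout.ca3_py, kc["ca3_ip"],
                                    fp["ca3_ip"], rng, "ca3_gaba_ip",
                                    distinct=False)
    tables = {"pp": t_pp, "pi": t_pi, "ip": t_ip}
    if cfg.wants_cortex():
        tables["mf_py"] = build_uniform_projection(
            layout.cortex_py, layout.ca3_py, cfg.k_dg_py, rng, "MF_to_PY")
        tables["mf_in"] = build_uniform_projection(
            layout.cortex_py, layout.ca3_in, cfg.k_dg_in, rng, "MF_to_IN")
    return tables


def build_ca1_wiring(cfg: ScenarioConfig, rng: np.random.Generator,
                     layout: NetworkLayout = DEFAULT_LAYOUT):
    fp = cfg.footprints
    kc = cfg.k_counts
    tables = {
        "pi": build_gaussian_footprint(layout.ca1_py, layout.ca1_in,
                                       kc["ca1_pi"], fp["ca1_pi"], rng,
                                       "ca1_ampa_pi"),
        "ip": build_gaussian_footprint(layout.ca1_in, layout.ca1_py,
                                       kc["ca1_ip"], fp["ca1_ip"], rng,
                                       "ca1_gaba_ip", distinct=False),
        "ii": build_gaussian_footprint(layout.ca1_in, layout.ca1_in,
                                       kc["ca1_ii"], fp["ca1_ii"], rng,
                                       "ca1_gaba_ii", distinct=False),
    }
    schaffer_cells = None
    if cfg.wants_schaffer():
        raw = build_schaffer_projection(layout.ca3_py, layout.ca1_py,
                                        layout.ca1_in, kc["schaffer"],
                                        fp["schaffer"], rng)
        rule = cfg.schaffer_rule
        schaffer, schaffer_cells = assign_schaffer_multiplicities(
            raw, rule, rng, n_ca1_py=layout.ca1_py.n)
        tables["schaffer"] = schaffer
    if cfg.wants_ta():
        tables["ta_py"] = build_uniform_projection(
            layout.cortex_py, layout.ca1_py, cfg.k_ec_py, rng, "TA_to_PY")
        tables["ta_in"] = build_uniform_projection(
            layout.cortex_py, layout.ca1_in, cfg.k_ec_in, rng, "TA_to_IN")
    return tables, schaffer_cells


def _chan_py(area_cm2, names):
    """(g, E, tau, comp) vectors for the four PY channels from kind names."""
    g = np.zeros(4); E = np.zeros(4); tau = np.ones(4)
    comp = np.zeros(4, dtype=np.int64)
    for ch, nm in enumerate(names):
        if nm is None:
            continue
        k = get_synapse_kind(nm)
        g[ch] = _density(k.g_nS, area_cm2)
        E[ch] = k.E_mV
        tau[ch] = k.tau_ms
        comp[ch] = 1 if k.target == "dend" else 0
    return g, E, tau, comp


def _chan_in(area_cm2, names):
    g = np.zeros(4); E = np.zeros(4); tau = np.ones(4)
    for ch, nm in enumerate(names):
        if nm is None:
            continue
        k = get_synapse_kind(nm)
        g[ch] = _density(k.g_nS, area_cm2)
        E[ch] = k.E_mV
        tau[ch] = k.tau_ms
    return g, E, tau


def _run_ca_stage(cfg, region, wiring, stream1, stream2, ss,
                  layout=DEFAULT_LAYOUT, record_site=False,
                  record_site_s=False):
    """Integrate one CA network (region in {"ca3", "ca1"})."""
    ppar = load_cell_params("ca_pyramidal_pinsky_rinzel")
    ipar = load_cell_params("ca_interneuron_wang_buzsaki")
    pop_py = getattr(layout, f"{region}_py")
    pop_in = getattr(layout, f"{region}_in")
    n_py, n_in = pop_py.n, pop_in.n
    dt = cfg.dt_ms
    n_steps = int(round(cfg.duration_s * 1000.0 / dt))
    rec_stride = int(round(1.0 / dt))
    n_frames = n_steps // rec_stride
    rng = np.random.default_rng(ss.spawn(1)[0])

    area_comp = 0.5 * ppar["area_total"] * _MM2_TO_CM2
    area_in = ipar["area"] * _MM2_TO_CM2

    if region == "ca3":
        py_names = ["ca3_ampa_pp", "ca3_gaba_ip", "MF_to_PY", None]
        in_names = ["ca3_ampa_pi", None, "MF_to_IN", None]
    else:
        py_names = [None, "ca1_gaba_ip", "schaffer_py", "TA_to_PY"]
        in_names = ["ca1_ampa_pi", "ca1_gaba_ii", "schaffer_in", "TA_to_IN"]
    g_py, E_py, tau_py, comp_py = _chan_py(area_comp, py_names)
    g_in, E_in, tau_in = _chan_in(area_in, in_names)

    def csr(name, n_src, kind):
        if name not in wiring:
            return csr_empty(n_src)
        t = wiring[name]
        if len(t) == 0:
            return csr_empty(n_src)
        return t.to_csr(n_src, _weights(t, kind))

    pp = csr("pp", n_py, "ca3_ampa_pp")
    pi_ = csr("pi", n_py, "ca3_ampa_pi" if region == "ca3" else "ca1_ampa_pi")
    ip = csr("ip", n_in, "ca3_gaba_ip" if region == "ca3" else "ca1_gaba_ip")
    ii = csr("ii", n_in, "ca1_gaba_ii")

    n_ctx = layout.cortex_py.n
    if region == "ca3":
        e1p = csr("mf_py", n_ctx, "MF_to_PY")
        e1i = csr("mf_in", n_ctx, "MF_to_IN")
        e2p = csr_empty(1); e2i = csr_empty(1)
    else:
        if "schaffer" in wiring:
            t = wiring["schaffer"]
            epy = t.edges[t.edges["synapse_kind"] == "schaffer_py"]
            ein = t.edges[t.edges["synapse_kind"] == "schaffer_in"]
            e1p = ConnectionTable(edges=epy.reset_index(drop=True)).to_csr(
                layout.ca3_py.n, _weights(
                    ConnectionTable(edges=epy.reset_index(drop=True)),
                    "schaffer_py"))
            e1i = ConnectionTable(edges=ein.reset_index(drop=True)).to_csr(
                layout.ca3_py.n, _weights(
                    ConnectionTable(edges=ein.reset_index(drop=True)),
                    "schaffer_in"))
        else:
            e1p = csr_empty(layout.ca3_py.n)
            e1i = csr_empty(layout.ca3_py.n)
        e2p = csr("ta_py", n_ctx, "TA_to_PY")
        e2i = csr("ta_in", n_ctx, "TA_to_IN")

    v0 = rng.uniform(-70.0, -60.0, n_py)
    sspy = _ss_pr(v0)
    Vs = v0.copy(); Vd = v0.copy()
    h = sspy["h"]; n_ = sspy["n"]; s = sspy["s"]; c = sspy["c"]
    q = np.full(n_py, 0.15)    # post-burst adapted start
    Ca = np.full(n_py, 0.2)
    vi0 = rng.uniform(-70.0, -60.0, n_in)
    ssin = _ss_wb(vi0)
    Vi = vi0.copy(); hi = ssin["h"]; ni = ssin["n"]

    cap_py = int(n_py * cfg.duration_s * 60) + 1000
    cap_in = int(n_in * cfg.duration_s * 250) + 1000
    spk_ps = np.zeros(cap_py, dtype=np.int64)
    spk_pi = np.zeros(cap_py, dtype=np.int64)
    spk_is = np.zeros(cap_in, dtype=np.int64)
    spk_ii = np.zeros(cap_in, dtype=np.int64)

    if record_site and region == "ca1":
        site_py = layout.recording_site_py.astype(np.int64)
        site_in = layout.recording_site_in.astype(np.int64)
        # conductance sum excludes Schaffer channels (ch2 on both populations)
        site_g_py = np.array([0.0, get_synapse_kind("ca1_gaba_ip").g_nS, 0.0,
                              get_synapse_kind("TA_to_PY").g_nS])
        site_g_in = np.array([get_synapse_kind("ca1_ampa_pi").g_nS,
                              get_synapse_kind("ca1_gaba_ii").g_nS, 0.0,
                              get_synapse_kind("TA_to_IN").g_nS])
    else:
        site_py = np.zeros(0, dtype=np.int64)
        site_in = np.zeros(0, dtype=np.int64)
        site_g_py = np.zeros(4); site_g_in = np.zeros(4)
    site_sig = np.zeros(n_frames)
    vin_site = np.zeros(n_frames)
    n_site = site_py.shape[0] + site_in.shape[0]
    site_s_rec = np.zeros((n_frames if (record_site_s and n_site) else 1,
                           max(n_site, 1), 4))

    noise = cfg.noise
    c_py, c_in = run_ca(
        dt, n_steps, rec_stride,
        pr_vector(ppar), wb_vector(ipar),
        np.full(n_in, ipar["g_L"]), np.full(n_in, ipar["E_L"]),
        g_py, E_py, tau_py, comp_py, g_in, E_in, tau_in,
        *pp, *pi_, *ip, *ii,
        stream1.steps, stream1.src, stream1.w, *e1p, *e1i,
        stream2.steps, stream2.src, stream2.w, *e2p, *e2i,
        np.full(n_py, noise[f"{region}_py"][0]),
        np.full(n_py, noise[f"{region}_py"][1]),
        np.full(n_in, noise[f"{region}_in"][0]),
        np.full(n_in, noise[f"{region}_in"][1]),
        _kernel_seed(ss.spawn(1)[0]),
        Vs, Vd, h, n_, s, c, q, Ca, Vi, hi, ni,
        np.zeros((4, n_py)), np.zeros((4, n_in)),
        spk_ps, spk_pi, spk_is, spk_ii,
        site_py, site_in, site_g_py, site_g_in,
        site_sig, vin_site, site_s_rec,
        np.zeros((n_frames, 0)), np.zeros(0, dtype=np.int64))
    if c_py >= cap_py or c_in >= cap_in:
        raise RuntimeError(f"{region} spike buffer saturated; raise the cap")
    out = {
        "py_steps": spk_ps[:c_py].copy(), "py_idx": spk_pi[:c_py].copy(),
        "in_steps": spk_is[:c_in].copy(), "in_idx": spk_ii[:c_in].copy(),
    }
    if record_site and region == "ca1":
        out["site_g"] = site_sig
        out["site_vin"] = vin_site
        if record_site_s:
            out["site_s"] = site_s_rec
            out["site_g_py"] = site_g_py
            out["site_g_in"] = site_g_in
    return out


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------


def run_scenario(cfg: ScenarioConfig,
                 layout: NetworkLayout = DEFAULT_LAYOUT,
                 record_site_s: bool = False,
                 cortex_stage: dict | None = None) -> SimulationResult:
    """Build all wiring dictated by the scenario and integrate it stage-wise.

    ``cortex_stage`` may carry the output of a previous cortical run with the
    same (config-compatible) seed and duration, to be reused across variants
    of the downstream wiring (the coupling is feedforward).
    """
    master = np.random.SeedSequence(cfg.seed)
    ss_wiring, ss_ctx, ss_ca3, ss_ca1 = master.spawn(4)
    rng_wiring = np.random.default_rng(ss_wiring)
    dt = cfg.dt_ms

    frames = []
    signals = {}
    n_cells = {}
    schaffer_cells = None

    if cfg.wants_cortex():
        if cortex_stage is None:
            ctx_wiring = build_cortex_wiring(cfg, rng_wiring, layout)
            cortex_stage = run_cortex_stage(cfg, ctx_wiring, ss_ctx, layout)
        else:
            # keep the wiring RNG stream aligned so downstream wiring matches
            build_cortex_wiring(cfg, rng_wiring, layout)
        frames.append(_spike_arrays(cortex_stage["py_steps"],
                                    cortex_stage["py_idx"],
                                    len(cortex_stage["py_steps"]),
                                    "ctx_py", dt))
        frames.append(_spike_arrays(cortex_stage["in_steps"],
                                    cortex_stage["in_idx"],
                                    len(cortex_stage["in_steps"]),
                                    "ctx_in", dt))
        signals["ctx_act"] = cortex_stage["lfp"]
        n_cells["ctx_py"] = layout.cortex_py.n
        n_cells["ctx_in"] = layout.cortex_in.n
        ctx_stream = _StreamPair(cortex_stage["py_steps"],
                                 cortex_stage["py_idx"])
    else:
        ctx_stream = _StreamPair()

    ca3_stage = None
    if cfg.wants_ca3():
        ca3_wiring = build_ca3_wiring(cfg, rng_wiring, layout)
        ca3_stage = _run_ca_stage(cfg, "ca3", ca3_wiring, ctx_stream,
                                  _StreamPair(), ss_ca3, layout)
        frames.append(_spike_arrays(ca3_stage["py_steps"],
                                    ca3_stage["py_idx"],
                                    len(ca3_stage["py_steps"]), "ca3_py", dt))
        frames.append(_spike_arrays(ca3_stage["in_steps"],
                                    ca3_stage["in_idx"],
                                    len(ca3_stage["in_steps"]), "ca3_in", dt))
        n_cells["ca3_py"] = layout.ca3_py.n
        n_cells["ca3_in"] = layout.ca3_in.n

    if cfg.wants_ca1():
        ca1_wiring, schaffer_cells = build_ca1_wiring(cfg, rng_wiring, layout)
        ca3_stream = (_StreamPair(ca3_stage["py_steps"], ca3_stage["py_idx"])
                      if ca3_stage is not None else _StreamPair())
        ca1_stage = _run_ca_stage(cfg, "ca1", ca1_wiring, ca3_stream,
                                  ctx_stream, ss_ca1, layout,
                                  record_site=True,
                                  record_site_s=record_site_s)
        frames.append(_spike_arrays(ca1_stage["py_steps"],
                                    ca1_stage["py_idx"],
                                    len(ca1_stage["py_steps"]), "ca1_py", dt))
        frames.append(_spike_arrays(ca1_stage["in_steps"],
                                    ca1_stage["in_idx"],
                                    len(ca1_stage["in_steps"]), "ca1_in", dt))
        n_cells["ca1_py"] = layout.ca1_py.n
        n_cells["ca1_in"] = layout.ca1_in.n
        signals["ca1_site_g"] = ca1_stage["site_g"]
        signals["ca1_site_vin"] = ca1_stage["site_vin"]
        extras = {k: ca1_stage[k] for k in ("site_s", "site_g_py", "site_g_in")
                  if k in ca1_stage}
    else:
        extras = {}

    spikes = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["time_ms", "population",
                                         "cell_index"]))
    spikes = spikes.sort_values(["time_ms", "population"],
                                kind="stable").reset_index(drop=True)
    return SimulationResult(
        spikes=spikes, signals=signals,
        duration_ms=cfg.duration_s * 1000.0, n_cells=n_cells, config=cfg,
        schaffer_cells=schaffer_cells,
        site_py=layout.recording_site_py, site_in=layout.recording_site_in,
        extras=extras)


# ---------------------------------------------------------------------------
# population rates and LFP proxies
# ---------------------------------------------------------------------------


def compute_population_rate(spike_times_ms, n_cells: int, duration_ms: float,
                            bin_ms: float = 30.0, overlap_ms: float = 0.0):
    """Population firing rate in Hz per cell from pooled spike times.

    Returns ``(bin_centers_ms, rate_hz)``.  ``overlap_ms`` sets the overlap of
    successive bins (0 = non-overlapping).
    """
    if bin_ms <= 0:
        raise ConfigurationError("bin_ms must be positive")
    if overlap_ms >= bin_ms:
        raise ConfigurationError("overlap_ms must be smaller than bin_ms")
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    stride = bin_ms - overlap_ms
    starts = np.arange(0.0, duration_ms - bin_ms + 0.5 * stride, stride)
    lo = np.searchsorted(t, starts)
    hi = np.searchsorted(t, starts + bin_ms)
    counts = (hi - lo).astype(float)
    rate = counts / (n_cells * bin_ms * 1e-3)
    return starts + 0.5 * bin_ms, rate


def compute_lfp_proxies(result: SimulationResult):
    """The cortical synaptic-activity signal and the CA1 recording-site
    conductance signal of a run (1 kHz each)."""
    ctx = result.signals.get("ctx_act")
    ca1 = result.signals.get("ca1_site_g")
    if ctx is None and ca1 is None:
        raise ConfigurationError(
            "run contains no LFP proxies; enable the cortical stage and/or "
            "the CA1 recording site")
    return ctx, ca1
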