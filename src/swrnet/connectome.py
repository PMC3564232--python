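"""Wiring construction for the cortical and CA3/CA1 networks.

Populations are one-dimensional equidistant arrays.  Within-network wiring
uses Gaussian footprints (connection probability falls off with the distance
between the source's homotopic position and the target), between-network
mossy-fiber and temporoammonic projections use uniform target sampling so
that cortical UP-state wave propagation is not imprinted on the hippocampus.
Each source emits an exact number of connections ``k_per_source``; repeated
draws of the same target are folded into the edge multiplicity.  Truncated
footprints at the array edges are renormalized (no wrap-around).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import ConfigurationError

EDGE_COLUMNS = ["source_population", "source_index", "target_population",
                "target_index", "synapse_kind", "multiplicity"]


@dataclass(frozen=True)
class Population:
    name: str
    n: int
    spacing_um: float

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n) * self.spacing_um

    @property
    def length_um(self) -> float:
        return (self.n - 1) * self.spacing_um


@dataclass(frozen=True)
class NetworkLayout:
    """Standard population sizes and geometry.

    The CA1 recording site is the central contiguous 560 um of the CA1 array:
    exactly 50 pyramidal cells and 6 interneurons, whose summed synaptic
    conductance stands in for a pyramidal-layer LFP electrode.
    """

    cortex_py: Population = Population("ctx_py", 1000, 5.0)
    cortex_in: Population = Population("ctx_in", 250, 20.0)
    ca3_py: Population = Population("ca3_py", 1000, 11.2)
    ca3_in: Population = Population("ca3_in", 100, 112.0)
    ca1_py: Population = Population("ca1_py", 1000, 11.2)
    ca1_in: Population = Population("ca1_in", 100, 112.0)

    @property
    def recording_site_py(self) -> np.ndarray:
        return np.arange(475, 525)

    @property
    def recording_site_in(self) -> np.ndarray:
        return np.arange(47, 53)


DEFAULT_LAYOUT = NetworkLayout()


@dataclass
class ConnectionTable:
    """Directed synaptic edges with per-edge multiplicity."""

    edges: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ConfigurationError(f"edge table missing columns: {missing}")

    def __len__(self):
        return len(self.edges)

    def out_degrees(self, n_src: int) -> np.ndarray:
        return np.bincount(self.edges["source_index"].to_numpy(),
                           minlength=n_src)

    def in_degrees(self, n_tgt: int) -> np.ndarray:
        return np.bincount(self.edges["target_index"].to_numpy(),
                           minlength=n_tgt)

    def to_csr(self, n_src: int, weights: np.ndarray | None = None):
        """CSR triple (indptr, target_idx, weight) ordered by source."""
        src = self.edges["source_index"].to_numpy(np.int64)
        tgt = self.edges["target_index"].to_numpy(np.int64)
        w = (self.edges["multiplicity"].to_numpy(float)
             if weights is None else np.asarray(weights, float))
        order = np.argsort(src, kind="stable")
        src, tgt, w = src[order], tgt[order], w[order]
        indptr = np.zeros(n_src + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, tgt, w

    def to_tsv(self, path):
        buf = io.StringIO()
        for k, v in self.meta.items():
            buf.write(f"# {k}: {v}\n")
        self.edges.to_csv(buf, sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "ConnectionTable":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                body_start = i + 1
            else:
                break
        edges = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
        return cls(edges=edges, meta=meta)


@dataclass(frozen=True)
class SchafferMultiplicityRule:
    """Synapses-per-Schaffer-connection: |N(mean, sd)| per pyramidal target
    (drawn once per cell), a fixed count for interneuron targets, and a
    strongly-driven flag above ``factor * mean``."""

    mean: float = 13.0
    sd: float = 13.0
    fixed_in: float = 13.0
    factor: float = 1.5

    @property
    def threshold(self) -> float:
        return self.factor * self.mean


BASELINE_SCHAFFER = SchafferMultiplicityRule(13.0, 13.0, 13.0)
INCREASED_SCHAFFER = SchafferMultiplicityRule(20.0, 20.0, 20.0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _sample_targets(rng, probs, k, distinct):
    n = probs.shape[0]
    if distinct:
        k_eff = min(k, int(np.count_nonzero(probs)))
        return rng.choice(n, size=k_eff, replace=False, p=probs)
    return rng.choice(n, size=k, replace=True, p=probs)


def _aggregate(src, tgt):
    """Collapse duplicate (src, tgt) pairs into multiplicity counts."""
    key = src.astype(np.int64) * np.int64(1 << 32) + tgt
    uniq, counts = np.unique(key, return_counts=True)
    return (uniq >> 32).astype(np.int64), \
        (uniq & ((1 << 32) - 1)).astype(np.int64), counts.astype(np.int64)


def build_gaussian_footprint(source_pop: Population, target_pop: Population,
                             k_per_source: int, footprint_sd: float,
                             seed, synapse_kind: str = "",
                             distinct: bool = True,
                             avoid_self: bool | None = None,
                             fixed: str = "out") -> ConnectionTable:
    """Wire cells with ``k_per_source`` connections drawn from a Gaussian
    profile centred on the homotopic position.

    With ``fixed="out"`` every source emits exactly ``k_per_source`` edges
    (hippocampal convention); with ``fixed="in"`` every target receives
    exactly that many (cortical convention).
    """
    if k_per_source < 0:
        raise ConfigurationError("k_per_source must be >= 0")
    if footprint_sd <= 0:
        raise ConfigurationError("footprint_sd must be positive")
    if fixed not in ("out", "in"):
        raise ConfigurationError("fixed must be 'out' or 'in'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    same = source_pop.name == target_pop.name
    if avoid_self is None:
        avoid_self = same
    xs = source_pop.positions
    xt = target_pop.positions
    scale = (target_pop.length_um / source_pop.length_um
             if source_pop.length_um > 0 else 1.0)
    all_src, all_tgt = [], []
    if fixed == "out":
        for i in range(source_pop.n):
            center = xs[i] * scale
            w = np.exp(-0.5 * ((xt - center) / footprint_sd) ** 2)
            if same and avoid_self:
                w[i] = 0.0
            tot = w.sum()
            if tot <= 0:
                raise ConfigurationError(
                    "footprint assigns no probability mass inside the array")
            tgt = _sample_targets(rng, w / tot, k_per_source, distinct)
            all_src.append(np.full(tgt.shape[0], i, dtype=np.int64))
            all_tgt.append(tgt.astype(np.int64))
    else:
        inv = 1.0 / scale if scale > 0 else 1.0
        for j in range(target_pop.n):
            center = xt[j] * inv
            w = np.exp(-0.5 * ((xs - center) / footprint_sd) ** 2)
            if same and avoid_self:
                w[j] = 0.0
            tot = w.sum()
            if tot <= 0:
                raise ConfigurationError(
                    "footprint assigns no probability mass inside the array")
            src = _sample_targets(rng, w / tot, k_per_source, distinct)
            all_tgt.append(np.full(src.shape[0], j, dtype=np.int64))
            all_src.append(src.astype(np.int64))
    if all_src and k_per_source > 0:
        src = np.concatenate(all_src)
        tgt = np.concatenate(all_tgt)
        src, tgt, mult = _aggregate(src, tgt)
    else:
        src = tgt = mult = np.zeros(0, dtype=np.int64)
    edges = pd.DataFrame({
        "source_population": source_pop.name, "source_index": src,
        "target_population": target_pop.name, "target_index": tgt,
        "synapse_kind": synapse_kind, "multiplicity": mult})
    meta = {"builder": "gaussian_footprint", "k_per_source": k_per_source,
            "footprint_sd_um": footprint_sd, "distinct": distinct,
            "fixed": fixed}
    return ConnectionTable(edges=edges, meta=meta)


def build_uniform_projection(source_pop: Population, target_pop: Population,
                             k_per_source: int, seed,
                             synapse_kind: str = "",
                             distinct: bool = True) -> ConnectionTable:
    """Wire each source to ``k_per_source`` targets sampled uniformly over the
    whole target array (mossy-fiber / temporoammonic convention)."""
    if k_per_source < 0:
        raise ConfigurationError("k_per_source must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    all_src, all_tgt = [], []
    if k_per_source > 0:
        for i in range(source_pop.n):
            if distinct:
                tgt = rng.choice(target_pop.n, size=min(k_per_source,
                                                        target_pop.n),
                                 replace=False)
            else:
                tgt = rng.integers(0, target_pop.n, size=k_per_source)
            all_src.append(np.full(tgt.shape[0], i, dtype=np.int64))
            all_tgt.append(tgt.astype(np.int64))
        src = np.concatenate(all_src)
        tgt = np.concatenate(all_tgt)
        src, tgt, mult = _aggregate(src, tgt)
    else:
        src = tgt = mult = np.zeros(0, dtype=np.int64)
    edges = pd.DataFrame({
        "source_population": source_pop.name, "source_index": src,
        "target_population": target_pop.name, "target_index": tgt,
        "synapse_kind": synapse_kind, "multiplicity": mult})
    meta = {"builder": "uniform_projection", "k_per_source": k_per_source,
            "distinct": distinct}
    return ConnectionTable(edges=edges, meta=meta)


def build_schaffer_projection(ca3_py: Population, ca1_py: Population,
                              ca1_in: Population, k_per_source: int,
                              footprint_sd: float, seed) -> ConnectionTable:
    """Schaffer collaterals: each CA3 pyramidal cell contacts ``k_per_source``
    CA1 neurons (pyramidal cells and interneurons jointly), Gaussian-centred
    on the homotopic CA1 position."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xs = ca3_py.positions
    x_all = np.concatenate([ca1_py.positions, ca1_in.positions])
    n_py = ca1_py.n
    all_rows = []
    for i in range(ca3_py.n):
        w = np.exp(-0.5 * ((x_all - xs[i]) / footprint_sd) ** 2)
        tgt = _sample_targets(rng, w / w.sum(), k_per_source, distinct=True)
        for t in tgt:
            if t < n_py:
                all_rows.append((i, "ca1_py", int(t), "schaffer_py"))
            else:
                all_rows.append((i, "ca1_in", int(t - n_py), "schaffer_in"))
    edges = pd.DataFrame(all_rows, columns=["source_index",
                                            "target_population",
                                            "target_index", "synapse_kind"])
    edges.insert(0, "source_population", "ca3_py")
    edges["multiplicity"] = 1
    meta = {"builder": "schaffer_projection", "k_per_source": k_per_source,
            "footprint_sd_um": footprint_sd}
    return ConnectionTable(edges=edges[EDGE_COLUMNS], meta=meta)


def assign_schaffer_multiplicities(table: ConnectionTable,
                                   rule: SchafferMultiplicityRule,
                                   seed, n_ca1_py: int = 1000):
    """Draw synapses-per-connection once per CA1 pyramidal target and apply it
    to all its incoming Schaffer edges; interneuron targets use the fixed
    value.  Returns ``(table, cell_table)`` where ``cell_table`` holds the
    per-cell sampled value, integer multiplicity and strongly-driven flag."""
    kinds = set(table.edges["synapse_kind"].unique())
    if not kinds <= {"schaffer_py", "schaffer_in"}:
        raise ConfigurationError(
            "assign_schaffer_multiplicities expects a pure Schaffer table")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    raw = np.abs(rng.normal(rule.mean, rule.sd, size=n_ca1_py))
    mult = np.maximum(1, _round_half_away(raw)).astype(np.int64)
    strongly = raw > rule.threshold
    cell_table = pd.DataFrame({
        "cell_index": np.arange(n_ca1_py),
        "raw_synapses_per_connection": raw,
        "multiplicity": mult,
        "strongly_driven": strongly,
    })
    edges = table.edges.copy()
    is_py = edges["synapse_kind"] == "schaffer_py"
    edges.loc[is_py, "multiplicity"] = \
        mult[edges.loc[is_py, "target_index"].to_numpy()]
    edges.loc[~is_py, "multiplicity"] = int(round(rule.fixed_in))
    meta = dict(table.meta)
    meta.update({"schaffer_mean": rule.mean, "schaffer_sd": rule.sd,
                 "schaffer_fixed_in": rule.fixed_in,
                 "strongly_driven_threshold": rule.threshold})
    return ConnectionTable(edges=edges, meta=meta), cell_table


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------


def pair_connectivity(table: ConnectionTable, n: int) -> float:
    """Probability that an unordered pair of cells in a recurrent table is
    connected in at least one direction."""
    e = table.edges
    a = e["source_index"].to_numpy(np.int64)
    b = e["target_index"].to_numpy(np.int64)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    n_pairs_connected = np.unique(lo * np.int64(n) + hi).shape[0]
    return n_pairs_connected / (n * (n - 1) / 2)


def cluster_connectivity(table: ConnectionTable, source_pop: Population,
                         target_pop: Population, footprint_sd: float,
                         half_width_sds: float = 2.0) -> float:
    """Mean probability that a source connects to a target inside its
    footprint cluster (targets within ``half_width_sds`` SD of the centre)."""
    xt = target_pop.positions
    scale = (target_pop.length_um / source_pop.length_um
             if source_pop.length_um > 0 else 1.0)
    e = table.edges
    probs = []
    by_src = e.groupby("source_index")["target_index"].unique()
    for i in range(source_pop.n):
        center = source_pop.positions[i] * scale
        in_cluster = np.abs(xt - center) <= half_width_sds * footprint_sd
        n_cluster = int(in_cluster.sum())
        if n_cluster == 0:
            continue
        tgts = by_src.get(i, np.zeros(0, dtype=np.int64))
        hit = int(np.isin(np.nonzero(in_cluster)[0], tgts).sum())
        probs.append(hit / n_cluster)
    return float(np.mean(probs)) if probs else 0.0


def connectome_summary(tables: dict[str, ConnectionTable],
                       pop_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Degree/multiplicity statistics for a set of connection tables."""
    rows = []
    for name, t in tables.items():
        e = t.edges
        if len(e) == 0:
            rows.append({"projection": name, "n_edges": 0, "n_synapses": 0,
                         "out_degree_mean": 0.0, "in_degree_mean": 0.0,
                         "multiplicity_mean": 0.0, "pair_connectivity": 0.0})
            continue
        src_pop = e["source_population"].iloc[0]
        tgt_pop = e["target_population"].iloc[0]
        n_src = (pop_sizes or {}).get(src_pop,
                                      int(e["source_index"].max()) + 1)
        n_tgt = (pop_sizes or {}).get(tgt_pop,
                                      int(e["target_index"].max()) + 1)
        row = {
            "projection": name,
            "n_edges": len(e),
            "n_synapses": int(e["multiplicity"].sum()),
            "out_degree_mean": len(e) / n_src,
            "in_degree_mean": len(e) / n_tgt,
            "multiplicity_mean": float(e["multiplicity"].mean()),
            "pair_connectivity": (pair_connectivity(t, n_src)
                                  if src_pop == tgt_pop else np.nan),
        }
        rows.append(row)
    return pd.DataFrame(rows)
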