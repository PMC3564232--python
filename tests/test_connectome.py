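"""Wiring construction: connectivity probabilities, degree bookkeeping,
Schaffer multiplicities, determinism."""

import numpy as np
import pytest
from scipy import stats

from swrnet.connectome import (BASELINE_SCHAFFER, DEFAULT_LAYOUT,
                               INCREASED_SCHAFFER, SchafferMultiplicityRule,
                               assign_schaffer_multiplicities,
                               build_gaussian_footprint,
                               build_schaffer_projection,
                               build_uniform_projection, cluster_connectivity,
                               connectome_summary, pair_connectivity)

L = DEFAULT_LAYOUT


def test_ca3_recurrent_pair_connectivity():
    """1000 CA3 pyramidal cells making 55 recurrent connections each yield
    ~10.62% probability that an unordered pair is connected >= once."""
    t = build_gaussian_footprint(L.ca3_py, L.ca3_py, 55, 8000.0, seed=7,
                                 synapse_kind="ca3_ampa_pp")
    p = pair_connectivity(t, 1000)
    assert p == pytest.approx(0.1062, abs=0.003)


def test_zero_k_gives_empty_table():
    t = build_gaussian_footprint(L.ca3_py, L.ca3_py, 0, 100.0, seed=0)
    assert len(t) == 0
    t2 = build_uniform_projection(L.cortex_py, L.ca3_in, 0, seed=0)
    assert len(t2) == 0


def test_ca1_py_to_in_cluster_connectivity():
    """20 connections per pyramidal cell onto interneurons give ~30%
    connectivity inside the footprint cluster (exhaustive pair count)."""
    t = build_gaussian_footprint(L.ca1_py, L.ca1_in, 20, 2400.0, seed=3,
                                 synapse_kind="ca1_ampa_pi")
    p = cluster_connectivity(t, L.ca1_py, L.ca1_in, 2400.0)
    assert p == pytest.approx(0.30, abs=0.05)


def test_uniform_projection_interneuron_in_degrees():
    """1000 cortical cells onto 100 interneurons: mean in-degree is
    10 x k_DG-IN."""
    for k, expect in ((1, 10.0), (10, 100.0)):
        t = build_uniform_projection(L.cortex_py, L.ca3_in, k, seed=11)
        in_deg = np.zeros(100)
        for _, row in t.edges.iterrows():
            in_deg[row["target_index"]] += row["multiplicity"]
        assert in_deg.mean() == pytest.approx(expect, rel=0.01)


def test_uniform_k1_in_degree_distribution_binomial():
    """k=1 onto an equal-size target: in-degrees ~ Binomial(1000, 1/1000),
    chi-squared against a direct multinomial sampling oracle."""
    t = build_uniform_projection(L.cortex_py, L.ca3_py, 1, seed=5)
    in_deg = t.in_degrees(1000)
    rng = np.random.default_rng(99)
    oracle = np.bincount(rng.integers(0, 1000, 1000), minlength=1000)
    bins = [-0.5, 0.5, 1.5, 2.5, 20]
    obs = np.histogram(in_deg, bins)[0]
    n = 1000
    pmf = stats.binom(n, 1 / n)
    expected = np.array([pmf.cdf(0.5), pmf.cdf(1.5) - pmf.cdf(0.5),
                         pmf.cdf(2.5) - pmf.cdf(1.5),
                         1 - pmf.cdf(2.5)]) * n
    chi2 = np.sum((obs - expected) ** 2 / expected)
    assert chi2 < stats.chi2(3).ppf(0.999)
    obs_oracle = np.histogram(oracle, bins)[0]
    chi2_oracle = np.sum((obs_oracle - expected) ** 2 / expected)
    assert chi2_oracle < stats.chi2(3).ppf(0.999)


def _schaffer(seed=13):
    return build_schaffer_projection(L.ca3_py, L.ca1_py, L.ca1_in, 130,
                                     1900.0, seed)


def test_schaffer_baseline_moderately_driven_fraction():
    """|N(13,13)| below the 19.5 threshold: ~70% of cells (analytic
    Phi(0.5) - Phi(-2.5) ~ 0.685)."""
    _, cells = assign_schaffer_multiplicities(_schaffer(), BASELINE_SCHAFFER,
                                              seed=21)
    frac = (cells["raw_synapses_per_connection"] < 19.5).mean()
    analytic = stats.norm.cdf(0.5) - stats.norm.cdf(-2.5)
    assert frac == pytest.approx(analytic, abs=0.02)
    assert (~cells["strongly_driven"]).mean() == pytest.approx(frac, abs=1e-9)


def test_schaffer_zero_sd_all_thirteen():
    rule = SchafferMultiplicityRule(13.0, 0.0, 13.0)
    tab, cells = assign_schaffer_multiplicities(_schaffer(), rule, seed=2)
    assert (cells["multiplicity"] == 13).all()
    assert (~cells["strongly_driven"]).all()
    is_py = tab.edges["synapse_kind"] == "schaffer_py"
    assert (tab.edges.loc[is_py, "multiplicity"] == 13).all()
    assert (tab.edges.loc[~is_py, "multiplicity"] == 13).all()


def test_schaffer_increased_strongly_driven_fraction_vs_oracle():
    """Strongly-driven fraction under |N(20,20)| vs a Monte-Carlo oracle of
    P(|X| > 30)."""
    _, cells = assign_schaffer_multiplicities(_schaffer(), INCREASED_SCHAFFER,
                                              seed=17)
    frac = cells["strongly_driven"].mean()
    rng = np.random.default_rng(1234)
    oracle = (np.abs(rng.normal(20, 20, 200000)) > 30).mean()
    assert frac == pytest.approx(oracle, abs=0.03)


def test_schaffer_multiplicity_shared_across_edges_of_a_target():
    tab, cells = assign_schaffer_multiplicities(_schaffer(), BASELINE_SCHAFFER,
                                                seed=4)
    e = tab.edges
    py = e[e["synapse_kind"] == "schaffer_py"]
    per_target = py.groupby("target_index")["multiplicity"].nunique()
    assert (per_target == 1).all()
    m = cells.set_index("cell_index")["multiplicity"]
    sample = py.head(500)
    assert (sample["multiplicity"].to_numpy()
            == m.loc[sample["target_index"]].to_numpy()).all()


def test_edge_count_conservation():
    t = build_gaussian_footprint(L.ca3_py, L.ca3_in, 5, 2000.0, seed=8)
    assert t.out_degrees(1000).sum() == len(t)
    assert t.in_degrees(100).sum() == len(t)


def test_seeded_determinism_byte_identical():
    a = build_gaussian_footprint(L.ca3_py, L.ca3_py, 55, 8000.0, seed=42)
    b = build_gaussian_footprint(L.ca3_py, L.ca3_py, 55, 8000.0, seed=42)
    assert a.edges.equals(b.edges)
    c = build_uniform_projection(L.cortex_py, L.ca3_py, 1, seed=42)
    d = build_uniform_projection(L.cortex_py, L.ca3_py, 1, seed=42)
    assert c.edges.equals(d.edges)


def test_footprint_distance_grows_with_sd():
    dists = []
    for sd in (200.0, 800.0, 3200.0):
        t = build_gaussian_footprint(L.ca3_py, L.ca3_py, 20, sd, seed=6)
        e = t.edges
        d = np.abs(L.ca3_py.positions[e["source_index"]]
                   - L.ca3_py.positions[e["target_index"]])
        dists.append(d.mean())
    assert dists[0] < dists[1] < dists[2]


def test_no_self_edges_in_recurrent_table():
    t = build_gaussian_footprint(L.ca3_py, L.ca3_py, 55, 8000.0, seed=1)
    assert (t.edges["source_index"] != t.edges["target_index"]).all()


def test_summary_reports_connectivity_and_conservation():
    tables = {
        "ca3_pp": build_gaussian_footprint(L.ca3_py, L.ca3_py, 55, 8000.0,
                                           seed=7, synapse_kind="ca3_ampa_pp"),
        "empty": build_gaussian_footprint(L.ca3_py, L.ca3_py, 0, 100.0,
                                          seed=0),
    }
    rep = connectome_summary(tables, {"ca3_py": 1000})
    row = rep[rep["projection"] == "ca3_pp"].iloc[0]
    assert row["pair_connectivity"] == pytest.approx(0.1062, abs=0.003)
    assert row["n_edges"] == row["out_degree_mean"] * 1000
    empty = rep[rep["projection"] == "empty"].iloc[0]
    assert empty["n_edges"] == 0 and empty["multiplicity_mean"] == 0.0


def test_roundtrip_tsv(tmp_path):
    t = build_uniform_projection(L.cortex_py, L.ca3_in, 2, seed=3,
                                 synapse_kind="MF_to_IN")
    p = tmp_path / "tab.tsv"
    t.to_tsv(p)
    from swrnet.connectome import ConnectionTable
    back = ConnectionTable.from_tsv(p)
    assert back.edges[["source_index", "target_index", "multiplicity"]].equals(
        t.edges[["source_index", "target_index", "multiplicity"]])
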