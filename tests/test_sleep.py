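"""Sleep classification pipeline and the synthetic dataset generator."""

import numpy as np
import pandas as pd
import pytest

from swrnet.cells import ConfigurationError
from swrnet.sleep import (SleepDataset, SyntheticSleepSpec, assign_groups,
                          classify_cell_state_pref, classify_dataset,
                          classify_ripple_state, compare_groups,
                          generate_synthetic_sleep_dataset,
                          peri_ripple_increase)


def _dataset(spikes_by_cell, transitions, ripples):
    rows = []
    for cell, times in spikes_by_cell.items():
        rows.append(pd.DataFrame({"cell_id": cell, "time_ms": times}))
    return SleepDataset(spikes=pd.concat(rows, ignore_index=True),
                        transitions=np.asarray(transitions, float),
                        ripples=np.asarray(ripples, float))


def test_constructed_up_and_down_cells():
    """A cell firing 0-200 ms after transitions is an UP-cell; one firing
    300-100 ms before is a DOWN-cell."""
    transitions = np.arange(1000.0, 31000.0, 1500.0)
    up_spikes = np.concatenate([tr + np.linspace(10, 200, 5)
                                for tr in transitions])
    down_spikes = np.concatenate([tr - np.linspace(100, 300, 5)
                                  for tr in transitions])
    ds = _dataset({0: up_spikes, 1: down_spikes}, transitions, [5000.0])
    pref = classify_cell_state_pref(ds).set_index("cell_id")
    assert pref.loc[0, "state_pref"] == "UP-cell"
    assert pref.loc[1, "state_pref"] == "DOWN-cell"


def test_cells_without_spikes_are_discarded_with_flag():
    transitions = np.arange(1000.0, 31000.0, 1500.0)
    ds = _dataset({0: transitions + 50.0, 1: np.array([100000.0])},
                  transitions, [5000.0])
    pref = classify_cell_state_pref(ds).set_index("cell_id")
    assert not pref.loc[0, "discarded"]
    assert pref.loc[1, "discarded"]
    assert pref.loc[1, "state_pref"] == "discarded"


def test_no_transitions_rejected():
    with pytest.raises(ConfigurationError):
        ds = _dataset({0: np.array([1.0])}, [1000.0], [500.0])
        classify_cell_state_pref(ds, min_transitions=10)


@pytest.mark.parametrize("offset,expected", [
    (-200.0, "DOWN"),   # 200 ms before the transition
    (-30.0, "UP"),      # too close to the transition
    (100.0, "UP"),      # after the transition
    (-400.0, "UP"),     # too far before
])
def test_ripple_state_assignment_window(offset, expected):
    transitions = np.array([10000.0, 20000.0, 30000.0])
    labels = classify_ripple_state(np.array([20000.0 + offset]), transitions)
    assert labels[0] == expected


def test_peri_ripple_curve_bin_count():
    """(200 - 5)/1 + 1 = 196 sliding windows per curve (index arithmetic)."""
    from swrnet.sleep import _sliding_curve
    centers, rate = _sliding_curve(np.array([0.0]), np.array([0.0]),
                                   100.0, 5.0, 1.0)
    n_expected = int((200 - 5) / 1) + 1
    assert centers.size == n_expected


def test_homogeneous_poisson_cell_has_no_increase(rng):
    """A constant-rate cell's peri-ripple increase is ~0 (the analytic
    value) up to sampling error."""
    duration = 600000.0
    transitions = np.arange(1000.0, duration, 1300.0)
    ripples = np.arange(5000.0, duration - 5000.0, 400.0)
    spikes = np.sort(rng.uniform(0, duration, int(duration * 8 / 1000)))
    ds = _dataset({0: spikes}, transitions, ripples)
    inc = peri_ripple_increase(ds).set_index("cell_id")
    # max-statistic bias of the sliding-window maximum stays bounded by a few
    # Hz at this ripple count; the planted bump below is an order larger
    assert abs(inc.loc[0, "increase_UP"]) < 4.0


def test_planted_bump_recovered():
    """A +20 Hz Gaussian bump (sigma 5 ms) at ripple peaks is recovered with
    a bias of ~2 Hz or less at n = 1000 ripples (mean over planted cells)."""
    r = np.random.default_rng(42)
    duration = 430000.0
    transitions = np.arange(1000.0, duration, 1300.0)
    ripples = np.arange(2000.0, duration - 2000.0, 420.0)[:1000]
    cells = {}
    for cell in range(8):
        base = r.uniform(0, duration, int(duration * 5 / 1000))
        n_b = r.poisson(20.0 * np.sqrt(2 * np.pi) * 5.0 / 1000.0,
                        ripples.size)
        bump = np.concatenate([rp + r.normal(0, 5.0, n)
                               for rp, n in zip(ripples, n_b)])
        cells[cell] = np.sort(np.concatenate([base, bump]))
    ds = _dataset(cells, transitions, ripples)
    inc = peri_ripple_increase(ds)
    assert inc["increase_UP"].mean() == pytest.approx(20.0, abs=2.0)


def test_all_equal_increases_give_all_low():
    pref = pd.DataFrame({"cell_id": [0, 1, 2],
                         "state_pref": "UP-cell",
                         "discarded": False, "peak_ms": 0.0})
    inc = pd.DataFrame({"cell_id": [0, 1, 2], "increase_UP": 5.0,
                        "increase_DOWN": 5.0, "discarded": False})
    with pytest.warns(UserWarning):
        out = assign_groups(pref, inc)
    assert (~out["highly_firing"]).all()
    assert (out["group"] == 2).all()


def test_group_semantics():
    pref = pd.DataFrame({"cell_id": [0, 1],
                         "state_pref": ["UP-cell", "DOWN-cell"],
                         "discarded": False, "peak_ms": 0.0})
    inc = pd.DataFrame({"cell_id": [0, 1],
                        "increase_UP": [50.0, 1.0],
                        "increase_DOWN": [50.0, 1.0],
                        "discarded": False})
    # add low-firing companions so the 1.5x-mean threshold is informative
    pref2 = pd.concat([pref, pd.DataFrame({
        "cell_id": [2, 3, 4, 5], "state_pref": ["UP-cell"] * 2 + ["DOWN-cell"] * 2,
        "discarded": False, "peak_ms": 0.0})], ignore_index=True)
    inc2 = pd.concat([inc, pd.DataFrame({
        "cell_id": [2, 3, 4, 5], "increase_UP": [2.0, 1.0, 30.0, 1.0],
        "increase_DOWN": [2.0, 1.0, 30.0, 1.0], "discarded": False})],
        ignore_index=True)
    out = assign_groups(pref2, inc2).set_index("cell_id")
    assert out.loc[0, "group"] == 1      # UP-cell, large increase
    assert out.loc[4, "group"] == 3      # DOWN-cell, large increase
    assert out.loc[5, "group"] == 4      # DOWN-cell, low increase


# ---------------------------------------------------------------------------
# synthetic generator end-to-end
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def synth_default():
    spec = SyntheticSleepSpec(duration_s=360.0,
                              group_counts={1: 75, 2: 250, 3: 50, 4: 125})
    ds, truth = generate_synthetic_sleep_dataset(spec, seed=11)
    return spec, ds, truth


def test_planted_up_ripple_fraction_recovered(synth_default):
    """The 90% planted UP-ripple share is recovered within 3 pp."""
    spec, ds, truth = synth_default
    labels = classify_ripple_state(ds.ripples, ds.transitions)
    frac = (labels == "UP").mean()
    planted = (truth["ripples"]["state"] == "UP").mean()
    assert frac == pytest.approx(planted, abs=0.03)
    assert planted == pytest.approx(spec.up_ripple_fraction, abs=0.03)


def test_state_preference_recovery(synth_default):
    """Planted UP/DOWN mixture recovered within a few percentage points."""
    spec, ds, truth = synth_default
    pref = classify_cell_state_pref(ds)
    m = pref.merge(truth["cells"], on="cell_id")
    ok = m[~m["discarded"]]
    agree = (ok["state_pref_x"] == ok["state_pref_y"]).mean()
    assert agree >= 0.95
    frac_up = (ok["state_pref_x"] == "UP-cell").mean()
    planted = (truth["cells"]["state_pref"] == "UP-cell").mean()
    assert frac_up == pytest.approx(planted, abs=0.03)


def test_group_label_recovery(synth_default):
    """>= 90% of planted group labels recovered by the full pipeline."""
    spec, ds, truth = synth_default
    cls = classify_dataset(ds)
    m = cls.merge(truth["cells"], on="cell_id")
    ok = m[~m["discarded"]]
    assert (ok["group_x"] == ok["group_y"]).mean() >= 0.90


def test_pipeline_invariant_under_time_translation(synth_default):
    spec, ds, truth = synth_default
    shift = 12345.0
    ds2 = SleepDataset(
        spikes=ds.spikes.assign(time_ms=ds.spikes["time_ms"] + shift),
        transitions=ds.transitions + shift, ripples=ds.ripples + shift)
    a = classify_dataset(ds).sort_values("cell_id").reset_index(drop=True)
    b = classify_dataset(ds2).sort_values("cell_id").reset_index(drop=True)
    assert (a["group"] == b["group"]).all()
    assert (a["state_pref"] == b["state_pref"]).all()


def test_halved_down_window_changes_few_groups(synth_default):
    """Halving the DOWN-ripple window to (-175, -60] ms changes group
    assignments for < 10% of cells."""
    spec, ds, truth = synth_default
    full = classify_dataset(ds)
    pref = classify_cell_state_pref(ds)
    labels_half = classify_ripple_state(ds.ripples, ds.transitions,
                                        window=(-175.0, -60.0))
    inc_half = peri_ripple_increase(ds, labels_half)
    half = assign_groups(pref, inc_half)
    m = full.merge(half, on="cell_id")
    ok = m[~(m["discarded_x"] | m["discarded_y"])]
    changed = (ok["group_x"] != ok["group_y"]).mean()
    assert changed < 0.10


def test_zero_gain_generator_gives_no_ripple_structure():
    """With all peri-ripple gains at zero the increase distribution carries
    no group signal (null model)."""
    spec = SyntheticSleepSpec(duration_s=120.0, bump_high_hz=0.0,
                              bump_low_hz=0.0,
                              group_counts={1: 30, 2: 30, 3: 20, 4: 20})
    ds, truth = generate_synthetic_sleep_dataset(spec, seed=5)
    inc = peri_ripple_increase(ds).merge(truth["cells"], on="cell_id")
    hi = inc[np.isin(inc["group"], (1, 3))]["increase_UP"].mean()
    lo = inc[np.isin(inc["group"], (2, 4))]["increase_UP"].mean()
    assert abs(hi - lo) < 3.0


def test_longer_recordings_shrink_estimator_error():
    """Doubling the duration reduces the spread of recovered increases
    (checked over several seeds)."""
    errs = {}
    for dur in (60.0, 240.0):
        vals = []
        for seed in range(6):
            spec = SyntheticSleepSpec(duration_s=dur,
                                      group_counts={1: 10, 2: 10, 3: 5, 4: 5})
            ds, truth = generate_synthetic_sleep_dataset(spec, seed=seed)
            inc = peri_ripple_increase(ds, min_ripples=5)
            m = inc.merge(truth["cells"], on="cell_id")
            g1 = m[m["group"] == 1]["increase_UP"].dropna()
            vals.extend(g1 - g1.mean())
        errs[dur] = np.std(vals)
    assert errs[240.0] < errs[60.0]


def test_negative_rates_rejected():
    with pytest.raises(ConfigurationError):
        SyntheticSleepSpec(rate_pref_hz=-1.0)


def test_compare_groups_t_test(synth_default):
    spec, ds, truth = synth_default
    cls = classify_dataset(ds).merge(truth["cells"], on="cell_id")
    g1 = cls[cls["group_y"] == 1]["increase_UP"]
    g2 = cls[cls["group_y"] == 2]["increase_UP"]
    df = pd.DataFrame({"a": g1.reset_index(drop=True),
                       "b": g2.reset_index(drop=True)})
    res = compare_groups(df, "a", "b")
    assert res["p"] < 0.001 and res["significant"]
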