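"""Sleep-recording classification pipeline.

Consumes spike tables, DOWN-to-UP transition times and ripple times (from a
simulation, the synthetic generator below, or external recordings) and
classifies every pyramidal cell by

* **state preference** -- the peri-transition firing-rate curve (350 ms
  around each DOWN-to-UP transition, 100 ms bins overlapping by 90 ms,
  mean-normalized) peaks before -60 ms (DOWN-cell) or after (UP-cell);
* **ripple firing** -- the peri-ripple rate curve (200 ms around each
  ripple, 5 ms bins overlapping by 4 ms); the firing-rate increase is the
  curve maximum minus the baseline (bins more than 40 ms from the ripple
  peak), computed separately over UP-ripples and DOWN-ripples;
* **group 1-4** -- the cross-tabulation of state preference with
  highly/low ripple firing (threshold: 1.5x the mean increase of same-state
  cells during same-state ripples).

Ripples are assigned to states via the nearest transition: events preceding
it by 60-350 ms are DOWN-ripples, all others UP-ripples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cells import ConfigurationError

# peri-transition state-preference analysis
TRANSITION_WINDOW_MS = 350.0
TRANSITION_BIN_MS = 100.0
TRANSITION_STRIDE_MS = 10.0
STATE_SPLIT_MS = -60.0
# peri-ripple analysis
RIPPLE_WINDOW_MS = 100.0
RIPPLE_BIN_MS = 5.0
RIPPLE_STRIDE_MS = 1.0
BASELINE_MARGIN_MS = 40.0
# ripple-state assignment window
DOWN_RIPPLE_WINDOW = (-350.0, -60.0)
HIGH_FIRING_FACTOR = 1.5


@dataclass
class SleepDataset:
    """Spike tables plus transition and ripple event times (ms)."""

    spikes: pd.DataFrame            # cell_id, time_ms
    transitions: np.ndarray         # DOWN-to-UP transition times, increasing
    ripples: np.ndarray             # ripple (spectral-peak) times
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.ripples = np.asarray(self.ripples, dtype=float)
        if np.any(np.diff(self.transitions) <= 0):
            raise ConfigurationError("transitions must be strictly increasing")

    def cell_ids(self) -> np.ndarray:
        return np.unique(self.spikes["cell_id"].to_numpy())

    def save(self, outdir):
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False)
        pd.DataFrame({"time_ms": self.transitions}).to_csv(
            out / "transitions.tsv", sep="\t", index=False)
        pd.DataFrame({"time_ms": self.ripples}).to_csv(
            out / "ripples.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir) -> "SleepDataset":
        import pathlib
        p = pathlib.Path(indir)
        return cls(
            spikes=pd.read_csv(p / "spikes.tsv", sep="\t"),
            transitions=pd.read_csv(p / "transitions.tsv",
                                    sep="\t")["time_ms"].to_numpy(),
            ripples=pd.read_csv(p / "ripples.tsv",
                                sep="\t")["time_ms"].to_numpy())


def _sliding_curve(spike_times, events, window, bin_ms, stride):
    """Mean event-aligned rate curve (Hz): bins of ``bin_ms`` stepped by
    ``stride`` across [-window, +window] around each event."""
    starts = np.arange(-window, window - bin_ms + 0.5 * stride, stride)
    centers = starts + 0.5 * bin_ms
    t = np.sort(np.asarray(spike_times, dtype=float))
    counts = np.zeros(starts.size)
    for ev in events:
        lo = np.searchsorted(t, ev + starts)
        hi = np.searchsorted(t, ev + starts + bin_ms)
        counts += hi - lo
    rate = counts / (len(events) * bin_ms * 1e-3) if len(events) else counts
    return centers, rate


def peri_transition_curves(dataset: SleepDataset,
                           min_transitions: int = 10):
    """Per-cell mean-normalized rate curves around DOWN-to-UP transitions."""
    if dataset.transitions.size == 0:
        raise ConfigurationError("dataset has no transitions")
    if dataset.transitions.size < min_transitions:
        raise ConfigurationError(
            f"need at least {min_transitions} transitions")
    by_cell = dataset.spikes.groupby("cell_id")["time_ms"]
    out = {}
    centers = None
    for cell, times in by_cell:
        centers, rate = _sliding_curve(
            times.to_numpy(), dataset.transitions, TRANSITION_WINDOW_MS,
            TRANSITION_BIN_MS, TRANSITION_STRIDE_MS)
        out[cell] = rate
    return centers, out


def classify_cell_state_pref(dataset: SleepDataset,
                             min_transitions: int = 10) -> pd.DataFrame:
    """UP-cell / DOWN-cell labels from the peri-transition rate maximum.

    The position of the curve maximum relative to -60 ms decides the label
    (ties broken toward the later bin, the UP side).  Cells with no spikes in
    any window are discarded (``discarded = True``).
    """
    centers, curves = peri_transition_curves(dataset, min_transitions)
    rows = []
    for cell, rate in curves.items():
        total = rate.sum()
        if total == 0:
            rows.append((cell, "discarded", True, np.nan))
            continue
        norm = rate / rate.mean()
        # latest bin achieving the maximum (ties toward the UP side)
        peak_idx = len(norm) - 1 - int(np.argmax(norm[::-1]))
        peak_ms = centers[peak_idx]
        label = "DOWN-cell" if peak_ms < STATE_SPLIT_MS else "UP-cell"
        rows.append((cell, label, False, peak_ms))
    return pd.DataFrame(rows, columns=["cell_id", "state_pref", "discarded",
                                       "peak_ms"])


def classify_ripple_state(ripple_times, transitions,
                          window=DOWN_RIPPLE_WINDOW) -> np.ndarray:
    """Label each ripple 'UP' or 'DOWN' from its nearest transition.

    A ripple preceding its nearest DOWN-to-UP transition by 60-350 ms lies in
    the DOWN state; everything else counts as an UP-ripple.
    """
    r = np.asarray(ripple_times, dtype=float)
    tr = np.asarray(transitions, dtype=float)
    if r.size == 0 or tr.size == 0:
        raise ConfigurationError("both ripples and transitions are required")
    idx = np.clip(np.searchsorted(tr, r), 0, tr.size - 1)
    idx_lo = np.clip(idx - 1, 0, tr.size - 1)
    d_hi = np.abs(tr[idx] - r)
    d_lo = np.abs(tr[idx_lo] - r)
    nearest = np.where(d_lo < d_hi, tr[idx_lo], tr[idx])
    delta = r - nearest
    is_down = (delta >= window[0]) & (delta < window[1])
    return np.where(is_down, "DOWN", "UP")


def peri_ripple_increase(dataset: SleepDataset, ripple_labels=None,
                         min_ripples: int = 10) -> pd.DataFrame:
    """Per-cell peri-ripple rate curves and maximal increase over baseline.

    The increase (curve maximum minus mean of bins more than 40 ms from the
    ripple peak) is computed separately for UP- and DOWN-ripples.  Cells
    without spikes in any window are flagged ``discarded``.
    """
    if dataset.ripples.size < min_ripples:
        raise ConfigurationError(f"need at least {min_ripples} ripples")
    if ripple_labels is None:
        ripple_labels = classify_ripple_state(dataset.ripples,
                                              dataset.transitions)
    ripple_labels = np.asarray(ripple_labels)
    by_cell = dataset.spikes.groupby("cell_id")["time_ms"]
    rows = []
    for cell, times in by_cell:
        t = times.to_numpy()
        rec = {"cell_id": cell}
        any_spk = False
        for lab in ("UP", "DOWN"):
            evs = dataset.ripples[ripple_labels == lab]
            if evs.size == 0:
                rec[f"increase_{lab}"] = np.nan
                continue
            centers, rate = _sliding_curve(t, evs, RIPPLE_WINDOW_MS,
                                           RIPPLE_BIN_MS, RIPPLE_STRIDE_MS)
            if rate.sum() > 0:
                any_spk = True
            base = rate[np.abs(centers) > BASELINE_MARGIN_MS]
            rec[f"increase_{lab}"] = float(rate.max() - base.mean())
        rec["discarded"] = not any_spk
        rows.append(rec)
    return pd.DataFrame(rows)


def assign_groups(state_pref: pd.DataFrame,
                  increases: pd.DataFrame,
                  factor: float = HIGH_FIRING_FACTOR) -> pd.DataFrame:
    """Cross-tabulate state preference with ripple firing into groups 1-4.

    ``highly_firing`` means the cell's increase during same-state ripples
    exceeds ``factor`` times the mean same-state increase of cells with the
    same state preference (negative increases enter the mean unclipped).
    Groups: 1 = UP/highly, 2 = UP/low, 3 = DOWN/highly, 4 = DOWN/low.
    """
    df = state_pref.merge(increases, on="cell_id", how="outer")
    df["discarded"] = df["discarded_x"].fillna(True) | \
        df["discarded_y"].fillna(True)
    df = df.drop(columns=["discarded_x", "discarded_y"])
    df["own_increase"] = np.where(df["state_pref"] == "UP-cell",
                                  df["increase_UP"], df["increase_DOWN"])
    df["highly_firing"] = False
    df["group"] = 0
    for lab, hi_grp, lo_grp in (("UP-cell", 1, 2), ("DOWN-cell", 3, 4)):
        sel = (df["state_pref"] == lab) & ~df["discarded"]
        if not sel.any():
            continue
        vals = df.loc[sel, "own_increase"]
        mean_inc = vals.mean()
        if vals.nunique() <= 1:
            import warnings
            warnings.warn(f"degenerate ripple increases for {lab}: "
                          "threshold is ill-defined")
        thr = factor * mean_inc
        hi = vals > thr
        df.loc[sel, "highly_firing"] = hi
        df.loc[sel, "group"] = np.where(hi, hi_grp, lo_grp)
    return df


def classify_dataset(dataset: SleepDataset) -> pd.DataFrame:
    """Full pipeline: state preference, ripple labels, increases, groups."""
    pref = classify_cell_state_pref(dataset)
    labels = classify_ripple_state(dataset.ripples, dataset.transitions)
    inc = peri_ripple_increase(dataset, labels)
    return assign_groups(pref, inc)


def compare_groups(classification: pd.DataFrame, col_a: str, col_b: str,
                   paired: bool = False, alpha: float = 0.001):
    """t-test on maximal rate increases between two columns/groups."""
    a = classification[col_a].dropna().to_numpy()
    b = classification[col_b].dropna().to_numpy()
    if paired:
        n = min(a.size, b.size)
        t, p = stats.ttest_rel(a[:n], b[:n])
    else:
        t, p = stats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha)}


# ---------------------------------------------------------------------------
# synthetic sleep data generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSleepSpec:
    """Planted parameters of the state- and ripple-modulated Poisson model.

    The generator emulates slow-wave-sleep spike trains: alternating UP/DOWN
    states below 1 Hz, state-dependent per-cell rates, ripples occurring
    preferentially in UP states, and transient Gaussian rate bumps locked to
    ripple peaks.  Group semantics follow the 4-group cross-tabulation:
    group 1 = UP-preferring / strong ripple bump, 2 = UP / weak, 3 = DOWN /
    strong, 4 = DOWN / weak.
    """

    duration_s: float = 600.0
    so_cycle_ms: float = 1210.0          # mean UP + DOWN duration (~0.83 Hz)
    transition_delay_ms: float = 70.0    # reported transitions lag UP onset
                                         # (threshold-crossing detection)
    up_fraction: float = 0.5             # mean UP share of the cycle
    duration_shape: float = 16.0         # gamma shape of state durations
    group_counts: dict = field(default_factory=lambda:
                               {1: 150, 2: 500, 3: 100, 4: 250})
    rate_pref_hz: float = 6.0            # rate in the preferred state
    rate_nonpref_hz: float = 0.8         # rate in the other state
    ripple_rate_up_hz: float = 0.9       # ripple occurrence rate in UP states
    up_ripple_fraction: float = 0.9      # planted share of UP-ripples
    bump_high_hz: float = 25.0           # peri-ripple bump peak, groups 1/3
    bump_low_hz: float = 1.5             # groups 2/4
    bump_sigma_ms: float = 5.0
    bump_jitter_ms: float = 2.0
    group3_up_attenuation: float = 0.4   # group-3 bump scale in UP-ripples

    def __post_init__(self):
        for nm in ("rate_pref_hz", "rate_nonpref_hz", "ripple_rate_up_hz",
                   "bump_high_hz", "bump_low_hz"):
            if getattr(self, nm) < 0:
                raise ConfigurationError(f"{nm} must be non-negative")


def generate_synthetic_sleep_dataset(spec: SyntheticSleepSpec | None = None,
                                     seed: int = 0):
    """Draw a synthetic dataset plus its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has ``cells`` (cell_id,
    group, state_pref) and ``ripples`` (time_ms, state) tables.
    """
    spec = spec or SyntheticSleepSpec()
    rng = np.random.default_rng(seed)
    total_ms = spec.duration_s * 1000.0

    # --- alternating UP/DOWN states (gamma-distributed durations)
    mean_up = spec.so_cycle_ms * spec.up_fraction
    mean_down = spec.so_cycle_ms - mean_up
    shape = spec.duration_shape
    ups = []          # (start, end)
    transitions = []
    t = 0.0
    state_up = False  # start in DOWN so the first transition is DOWN-to-UP
    while t < total_ms:
        if state_up:
            d = rng.gamma(shape, mean_up / shape)
            ups.append((t, min(t + d, total_ms)))
        else:
            d = rng.gamma(shape, mean_down / shape)
            if t + d < total_ms:
                transitions.append(t + d + spec.transition_delay_ms)
        t += d
        state_up = not state_up
    transitions = np.array(transitions)
    ups = [(s, e) for s, e in ups if e - s > 1.0]

    # --- ripples: homogeneous within UP states; DOWN-ripples are placed in
    # the 60-350 ms window before the upcoming transition (the regime the
    # state-assignment rule is built for)
    up_times = []
    for s, e in ups:
        n = rng.poisson(spec.ripple_rate_up_hz * (e - s) * 1e-3)
        up_times.extend(rng.uniform(s, e, n))
    up_times = np.sort(up_times)
    n_down = int(round(len(up_times) * (1.0 - spec.up_ripple_fraction)
                       / max(spec.up_ripple_fraction, 1e-9)))
    down_times = []
    if n_down and transitions.size:
        tr_pick = rng.choice(transitions, size=n_down)
        lo = -340.0 + spec.transition_delay_ms
        hi = -70.0
        down_times = tr_pick + rng.uniform(lo, hi, n_down)
        down_times = down_times[down_times > 0]
    ripples = np.concatenate([up_times, down_times])
    states = np.array(["UP"] * len(up_times) + ["DOWN"] * len(down_times))
    order = np.argsort(ripples)
    ripples, states = ripples[order], states[order]

    # --- cells
    groups = np.concatenate([np.full(n, g) for g, n in
                             sorted(spec.group_counts.items())])
    n_cells = groups.size
    up_pref = np.isin(groups, (1, 2))
    bump_peak = np.where(np.isin(groups, (1, 3)), spec.bump_high_hz,
                         spec.bump_low_hz)

    up_arr = np.array(ups) if ups else np.zeros((0, 2))
    up_dur_ms = float((up_arr[:, 1] - up_arr[:, 0]).sum()) if len(up_arr) else 0.0
    down_dur_ms = total_ms - up_dur_ms

    all_rows = []
    for cell in range(n_cells):
        r_up = spec.rate_pref_hz if up_pref[cell] else spec.rate_nonpref_hz
        r_down = spec.rate_nonpref_hz if up_pref[cell] else spec.rate_pref_hz
        # state-driven spikes
        n_up = rng.poisson(r_up * up_dur_ms * 1e-3)
        if len(up_arr) and n_up:
            w = (up_arr[:, 1] - up_arr[:, 0]) / up_dur_ms
            seg = rng.choice(len(up_arr), size=n_up, p=w)
            t_up = rng.uniform(up_arr[seg, 0], up_arr[seg, 1])
        else:
            t_up = np.zeros(0)
        n_down_spk = rng.poisson(r_down * down_dur_ms * 1e-3)
        t_down = []
        while len(t_down) < n_down_spk:
            cand = rng.uniform(0, total_ms, n_down_spk - len(t_down))
            if len(up_arr):
                in_up = np.zeros(cand.size, dtype=bool)
                i = np.searchsorted(up_arr[:, 0], cand, side="right") - 1
                ok = i >= 0
                in_up[ok] = cand[ok] < up_arr[i[ok], 1]
                cand = cand[~in_up]
            t_down.extend(cand)
        t_down = np.array(t_down[:n_down_spk])
        # ripple-locked bumps
        t_bump = []
        scale = np.ones(ripples.size)
        if groups[cell] == 3:
            scale = np.where(states == "UP", spec.group3_up_attenuation, 1.0)
        lam = (bump_peak[cell] * np.sqrt(2 * np.pi) * spec.bump_sigma_ms
               * 1e-3) * scale
        n_per = rng.poisson(lam)
        for rt, n_b in zip(ripples, n_per):
            if n_b:
                center = rt + rng.normal(0.0, spec.bump_jitter_ms)
                t_bump.extend(rng.normal(center, spec.bump_sigma_ms, n_b))
        times = np.concatenate([t_up, t_down, np.array(t_bump)])
        times = times[(times >= 0) & (times < total_ms)]
        all_rows.append(pd.DataFrame({"cell_id": cell,
                                      "time_ms": np.sort(times)}))
    spikes = pd.concat(all_rows, ignore_index=True)
    dataset = SleepDataset(spikes=spikes, transitions=transitions,
                           ripples=ripples,
                           meta={"generator": "synthetic_sleep", "seed": seed})
    truth = {
        "cells": pd.DataFrame({
            "cell_id": np.arange(n_cells),
            "group": groups,
            "state_pref": np.where(up_pref, "UP-cell", "DOWN-cell"),
        }),
        "ripples": pd.DataFrame({"time_ms": ripples, "state": states}),
        "up_states": up_arr,
    }
    return dataset, truth
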