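"""Correlation analyses on the model side: SO-cycle-aligned z-scored firing,
ripple-triggered histograms, and spike-ripple phase locking.

Conventions: the average SO cycle is aligned on the maximum of the cortical
activity signal (t = 0); cycles are resampled to the mean cycle length before
averaging.  Ripples are aligned on the minimum of the bandpassed recording
site signal; ripple phase is the analytic-signal (Hilbert) phase shifted so
that the bandpassed trough sits at -90 degrees, and phase locking against a
-90 degree mean direction is assessed with the circular V-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.signal import hilbert

from .cells import ConfigurationError
from .events import IntervalSet


@dataclass
class AlignedRateMatrix:
    """Per-cell mean firing rate over the average SO cycle.

    Rows are cells; columns span one mean cycle with t = 0 at the cycle's
    alignment reference (UP-state maximum).  Rows are z-scored; silent or
    constant-rate cells are excluded (``labels.included == False``).
    """

    matrix: np.ndarray            # (n_included, n_bins) z-scored
    time_ms: np.ndarray           # bin centres relative to the alignment point
    order: np.ndarray             # included-cell permutation by peak time
    up_mask: np.ndarray           # per-bin: does the bin fall in the mean UP?
    labels: pd.DataFrame          # cell_index, included, peak_ms, up_preferring
    n_cycles: int = 0
    meta: dict = field(default_factory=dict)


def align_rates_to_cycles(spike_times_ms, spike_cells, n_cells: int,
                          cycles: IntervalSet,
                          up_states: IntervalSet | None = None,
                          bin_ms: float = 30.0,
                          min_cycles: int = 5) -> AlignedRateMatrix:
    """Average each cell's firing over all SO cycles and z-score it.

    Each cycle is linearly resampled to the mean cycle length, aligned on its
    reference point (``cycles.peaks``).  A cell is UP-preferring when its
    peak bin falls inside the mean-cycle UP region (bins that lie within a
    detected UP state in the majority of cycles).
    """
    if len(cycles) < min_cycles:
        raise ConfigurationError(
            f"need at least {min_cycles} SO cycles, got {len(cycles)}")
    t = np.asarray(spike_times_ms, dtype=float)
    c = np.asarray(spike_cells, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]

    mean_len = float(np.mean(cycles.durations))
    n_bins = max(4, int(round(mean_len / bin_ms)))
    counts = np.zeros((n_cells, n_bins))
    up_votes = np.zeros(n_bins)
    starts, ends, refs = cycles.starts, cycles.ends, cycles.peaks
    # alignment: the reference point maps to a fixed phase = mean relative
    # position of the reference across cycles
    ref_phase = float(np.mean((refs - starts) / (ends - starts)))
    for s, e, r in zip(starts, ends, refs):
        i0, i1 = np.searchsorted(t, [s, e])
        phases = (t[i0:i1] - s) / (e - s)
        b = np.minimum((phases * n_bins).astype(int), n_bins - 1)
        np.add.at(counts, (c[i0:i1], b), 1.0)
        if up_states is not None and len(up_states):
            centers = s + (np.arange(n_bins) + 0.5) / n_bins * (e - s)
            up_votes += up_states.contains(centers)
    n_cyc = len(cycles)
    rate = counts / (n_cyc * (mean_len / n_bins) * 1e-3)   # Hz
    sd = rate.std(axis=1)
    included = sd > 0
    z = np.zeros_like(rate)
    z[included] = ((rate[included] - rate[included].mean(axis=1, keepdims=True))
                   / sd[included, None])
    # roll so the alignment reference sits at t = 0
    shift = int(round(ref_phase * n_bins))
    z = np.roll(z, -shift + n_bins // 2, axis=1)
    up_mask = np.roll(up_votes / n_cyc > 0.5, -shift + n_bins // 2)
    time_ms = (np.arange(n_bins) - n_bins // 2 + 0.5) * (mean_len / n_bins)

    peak_bin = np.argmax(z, axis=1)
    peak_ms = time_ms[peak_bin]
    up_pref = up_mask[peak_bin] & included
    labels = pd.DataFrame({
        "cell_index": np.arange(n_cells),
        "included": included,
        "peak_ms": np.where(included, peak_ms, np.nan),
        "up_preferring": up_pref,
    })
    inc_idx = np.nonzero(included)[0]
    order_idx = inc_idx[np.argsort(peak_bin[included], kind="stable")]
    return AlignedRateMatrix(matrix=z[included], time_ms=time_ms,
                             order=order_idx, up_mask=up_mask, labels=labels,
                             n_cycles=n_cyc,
                             meta={"bin_ms": bin_ms, "mean_len_ms": mean_len})


# ---------------------------------------------------------------------------
# ripple-triggered statistics
# ---------------------------------------------------------------------------


@dataclass
class RippleTriggeredHistogram:
    lags_ms: np.ndarray
    counts: np.ndarray
    avg_waveform: np.ndarray      # bandpassed signal averaged over ripples
    n_ripples: int
    n_spikes: int
    participation: float          # mean fraction of subset cells per ripple


def ripple_triggered_histogram(spike_times_ms, spike_cells, cell_subset,
                               ripples: IntervalSet, bandpassed,
                               fs_hz: float = 1000.0,
                               window_ms: float = 75.0,
                               bin_ms: float = 1.0,
                               min_ripples: int = 5
                               ) -> RippleTriggeredHistogram:
    """Spike histogram of a cell subset around aligned ripple minima, plus
    the average ripple waveform over the same window."""
    if len(ripples) < min_ripples:
        raise ConfigurationError(
            f"need at least {min_ripples} ripples, got {len(ripples)}")
    subset = np.asarray(cell_subset)
    if subset.size == 0:
        raise ConfigurationError("empty cell subset")
    t = np.asarray(spike_times_ms, dtype=float)
    c = np.asarray(spike_cells)
    sel = np.isin(c, subset)
    t, c = t[sel], c[sel]
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]

    edges = np.arange(-window_ms, window_ms + bin_ms, bin_ms)
    lags = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(lags.size)
    bp = np.asarray(bandpassed, dtype=float)
    nw = int(round(window_ms * fs_hz / 1000.0))
    wave = np.zeros(2 * nw + 1)
    n_wave = 0
    n_spk = 0
    part = []
    for (s, e, pk) in zip(ripples.starts, ripples.ends, ripples.peaks):
        i0, i1 = np.searchsorted(t, [pk - window_ms, pk + window_ms])
        counts += np.histogram(t[i0:i1] - pk, bins=edges)[0]
        n_spk += i1 - i0
        j0, j1 = np.searchsorted(t, [s, e])
        part.append(np.unique(c[j0:j1]).size / subset.size)
        k = int(round(pk * fs_hz / 1000.0))
        if k - nw >= 0 and k + nw + 1 <= bp.size:
            wave += bp[k - nw:k + nw + 1]
            n_wave += 1
    if n_wave:
        wave /= n_wave
    return RippleTriggeredHistogram(
        lags_ms=lags, counts=counts, avg_waveform=wave,
        n_ripples=len(ripples), n_spikes=int(n_spk),
        participation=float(np.mean(part)))


def ripple_participation(spike_times_ms, spike_cells, n_cells: int,
                         ripples: IntervalSet) -> float:
    """Mean fraction of cells (out of ``n_cells``) firing per ripple event."""
    t = np.asarray(spike_times_ms, dtype=float)
    c = np.asarray(spike_cells)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    fr = []
    for s, e in zip(ripples.starts, ripples.ends):
        i0, i1 = np.searchsorted(t, [s, e])
        fr.append(np.unique(c[i0:i1]).size / n_cells)
    return float(np.mean(fr)) if fr else 0.0


# ---------------------------------------------------------------------------
# phase locking
# ---------------------------------------------------------------------------


@dataclass
class PhaseLockingResult:
    """Spike phases on the average ripple and the V-test against -90 deg."""

    phases_deg: np.ndarray
    p_value: float
    v_stat: float
    mean_direction_deg: float
    n: int
    underpowered: bool

    @property
    def significant(self) -> bool:
        return (not self.underpowered) and self.p_value < 0.05


def waveform_phase(waveform, lags_ms, at=None) -> np.ndarray:
    """Instantaneous phase (deg) of a band-limited waveform, shifted so that
    troughs sit at -90 degrees.

    With ``at``, the unwrapped phase is linearly interpolated at those lag
    values (avoids grid-snapping bias in phase statistics).
    """
    w = np.asarray(waveform, dtype=float)
    phi = np.unwrap(np.angle(hilbert(w - w.mean())))
    if at is not None:
        phi = np.interp(np.asarray(at, dtype=float),
                        np.asarray(lags_ms, dtype=float), phi)
    deg = np.degrees(phi) + 90.0 + 180.0
    return (deg % 360.0) - 180.0


def vtest(phases_deg, mean_direction_deg: float = -90.0):
    """Circular V-test for non-uniformity with a specified mean direction.

    Returns ``(v_statistic, p_value)``."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    v, pval = pg.circ_vtest(rad, dir=np.radians(mean_direction_deg))
    return float(v), float(pval)


def phase_locking_test(spike_lags_ms, avg_waveform, lags_ms,
                       mean_direction_deg: float = -90.0,
                       min_spikes: int = 10) -> PhaseLockingResult:
    """V-test for non-uniformity of spike phases with the stated mean
    direction (-90 deg = ripple trough).

    ``spike_lags_ms`` are spike times relative to the aligned ripple minimum;
    each is mapped to the instantaneous phase of the average waveform.
    """
    lags = np.asarray(lags_ms, dtype=float)
    sl = np.asarray(spike_lags_ms, dtype=float)
    sl = sl[(sl >= lags[0]) & (sl <= lags[-1])]
    phases = waveform_phase(avg_waveform, lags, at=sl)
    n = phases.size
    under = n < min_spikes
    if n == 0:
        return PhaseLockingResult(np.zeros(0), 1.0, 0.0, float("nan"), 0,
                                  True)
    v, pval = vtest(phases, mean_direction_deg)
    mean_dir = np.degrees(pg.circ_mean(np.radians(phases)))
    return PhaseLockingResult(phases_deg=phases, p_value=pval, v_stat=v,
                              mean_direction_deg=float(mean_dir), n=int(n),
                              underpowered=bool(under))
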