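"""Detection of UP states, SO cycles, CA3 population bursts, and ripples.

All thresholds are expressed in units of the standard deviation of the
respective signal computed over the whole recording (events included).  The
ripple band is isolated with a zero-phase forward-backward 4th-order
Butterworth filter (150-200 Hz); the band edges are part of the detector
definition, the filter family is a package choice documented in
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cells import ConfigurationError

RIPPLE_BAND = (150.0, 200.0)


@dataclass
class IntervalSet:
    """Detected events of one kind as (start, end, peak) times in ms."""

    events: pd.DataFrame  # columns: kind, start_ms, end_ms, peak_ms
    kind: str = ""
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, kind, starts, ends, peaks=None, **meta):
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if peaks is None:
            peaks = 0.5 * (starts + ends)
        df = pd.DataFrame({"kind": kind, "start_ms": starts, "end_ms": ends,
                           "peak_ms": np.asarray(peaks, dtype=float)})
        if np.any(df["end_ms"].to_numpy() <= df["start_ms"].to_numpy()):
            raise ConfigurationError("interval end must exceed start")
        return cls(events=df, kind=kind, meta=meta)

    def __len__(self):
        return len(self.events)

    @property
    def starts(self) -> np.ndarray:
        return self.events["start_ms"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.events["end_ms"].to_numpy()

    @property
    def peaks(self) -> np.ndarray:
        return self.events["peak_ms"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def contains(self, times_ms) -> np.ndarray:
        """Boolean mask: does each time fall inside any interval
        (half-open [start, end))."""
        t = np.asarray(times_ms, dtype=float)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] < self.ends[idx[ok]]
        return out

    def to_tsv(self, path):
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            self.events.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IntervalSet":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                start = i + 1
            else:
                break
        import io
        df = pd.read_csv(io.StringIO("".join(lines[start:])), sep="\t")
        kind = df["kind"].iloc[0] if len(df) else ""
        return cls(events=df, kind=kind, meta=meta)


def merge_intervals(starts, ends, max_gap_ms):
    """Merge intervals whose gap to the next one is smaller than
    ``max_gap_ms``.  Input must be sorted by start; merging is associative."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if starts.size == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - out_e[-1] < max_gap_ms:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def _threshold_epochs(x, thr):
    """(start_idx, end_idx) of runs where x > thr (half-open)."""
    above = x > thr
    d = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    return np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]


# ---------------------------------------------------------------------------
# UP states and SO cycles
# ---------------------------------------------------------------------------

UP_THRESHOLD_FACTOR = {"synaptic_current": 0.45, "firing_rate": 0.2}


def detect_up_states(signal, fs_hz: float = 1000.0,
                     mode: str = "synaptic_current",
                     merge_gap_ms: float = 100.0) -> IntervalSet:
    """Threshold-crossing UP states of a cortical activity signal.

    The threshold is ``0.45 x SD`` of the signal for the synaptic-current
    proxy or ``0.2 x SD`` for the population firing rate; epochs closer than
    ``merge_gap_ms`` are taken as one.
    """
    if mode not in UP_THRESHOLD_FACTOR:
        raise ConfigurationError(f"unknown UP-state mode {mode!r}")
    x = np.asarray(signal, dtype=float)
    if x.size < fs_hz:
        raise ConfigurationError("signal shorter than 1 s equivalent")
    sd = x.std()
    if sd == 0.0:
        warnings.warn("zero-variance signal: no UP states detectable")
        return IntervalSet.from_arrays("UP_state", [], [])
    thr = UP_THRESHOLD_FACTOR[mode] * sd
    ms_per = 1000.0 / fs_hz
    si, ei = _threshold_epochs(x, thr)
    starts = si * ms_per
    ends = ei * ms_per
    starts, ends = merge_intervals(starts, ends, merge_gap_ms)
    peaks = []
    for s, e in zip(starts, ends):
        i0, i1 = int(s / ms_per), max(int(e / ms_per), int(s / ms_per) + 1)
        peaks.append((i0 + int(np.argmax(x[i0:i1]))) * ms_per)
    return IntervalSet.from_arrays("UP_state", starts, ends, peaks,
                                   threshold=thr, mode=mode, sd=sd)


def extract_so_cycles(up_states: IntervalSet, signal=None,
                      fs_hz: float = 1000.0) -> IntervalSet:
    """Slow-oscillation cycles: one DOWN followed by one UP.

    A cycle runs from the end of one detected UP state to the end of the
    next.  The cycle's alignment reference (``peak_ms``, t = 0 of the average
    cycle) is the time of the maximum of ``signal`` within the cycle; without
    a signal, the peak of the closing UP state is used.
    """
    if len(up_states) < 2:
        return IntervalSet.from_arrays("SO_cycle", [], [])
    ends = up_states.ends
    peaks_up = up_states.peaks
    starts = ends[:-1]
    stops = ends[1:]
    refs = []
    ms_per = 1000.0 / fs_hz
    for i, (s, e) in enumerate(zip(starts, stops)):
        if signal is not None:
            i0, i1 = int(s / ms_per), max(int(e / ms_per), int(s / ms_per) + 1)
            x = np.asarray(signal, dtype=float)
            refs.append((i0 + int(np.argmax(x[i0:i1]))) * ms_per)
        else:
            refs.append(peaks_up[i + 1])
    return IntervalSet.from_arrays("SO_cycle", starts, stops, refs)


def so_frequency(cycles: IntervalSet) -> float:
    """Inverse mean cycle duration in Hz."""
    if len(cycles) == 0:
        return float("nan")
    return 1000.0 / float(np.mean(cycles.durations))


# ---------------------------------------------------------------------------
# CA3 population bursts
# ---------------------------------------------------------------------------


def detect_ca3_bursts(rate, bin_ms: float = 10.0, onset_sd: float = 1.5,
                      boundary_sd: float = 1.2) -> IntervalSet:
    """Population bursts from the CA3 pyramidal rate in 10 ms bins.

    Onset wherever the rate exceeds ``1.5 x SD``; boundaries extended to
    where it drops below ``1.2 x SD``; overlapping extents merged.
    """
    r = np.asarray(rate, dtype=float)
    sd = r.std()
    if sd == 0.0:
        return IntervalSet.from_arrays("CA3_burst", [], [])
    hi = onset_sd * sd
    lo = boundary_sd * sd
    si, ei = _threshold_epochs(r, hi)
    starts, ends, peaks = [], [], []
    for s, e in zip(si, ei):
        while s > 0 and r[s - 1] > lo:
            s -= 1
        while e < r.size and r[e] > lo:
            e += 1
        if starts and s * bin_ms <= ends[-1]:
            ends[-1] = e * bin_ms
            pk = starts[-1] / bin_ms + np.argmax(
                r[int(starts[-1] / bin_ms):e])
            peaks[-1] = pk * bin_ms + 0.5 * bin_ms
            continue
        starts.append(s * bin_ms)
        ends.append(e * bin_ms)
        peaks.append((s + int(np.argmax(r[s:e]))) * bin_ms + 0.5 * bin_ms)
    return IntervalSet.from_arrays("CA3_burst", starts, ends, peaks,
                                   onset=hi, boundary=lo, bin_ms=bin_ms)


def burst_participation(bursts: IntervalSet, spike_times_ms, spike_cells,
                        n_cells: int) -> np.ndarray:
    """Per-burst fraction of distinct cells spiking within the boundaries."""
    t = np.asarray(spike_times_ms, dtype=float)
    c = np.asarray(spike_cells)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    out = []
    for s, e in zip(bursts.starts, bursts.ends):
        i0, i1 = np.searchsorted(t, [s, e])
        out.append(np.unique(c[i0:i1]).size / n_cells)
    return np.array(out)


# ---------------------------------------------------------------------------
# ripples
# ---------------------------------------------------------------------------


def bandpass_ripple(signal, fs_hz: float, band=RIPPLE_BAND) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass of the LFP proxy."""
    if fs_hz < 2.0 * band[1]:
        raise ConfigurationError(
            f"sampling rate {fs_hz} Hz cannot resolve the {band} Hz band")
    sos = sps.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def detect_ripples(site_signal, fs_hz: float = 1000.0,
                   rms_bin_ms: float = 10.0, band=RIPPLE_BAND,
                   onset_sd: float = 3.0, boundary_sd: float = 2.0,
                   min_duration_ms: float = 20.0,
                   merge_gap_ms: float = 10.0) -> IntervalSet:
    """Ripple events from the recording-site synaptic conductance signal.

    The 150-200 Hz bandpassed signal's RMS in 10 ms bins (50% overlap) is
    thresholded at ``mean + 3 x SD`` with boundaries at ``mean + 2 x SD``
    (the RMS has a nonzero floor, so thresholds are above the mean); events shorter
    than 20 ms are discarded and neighbours closer than 10 ms are merged.
    ``peak_ms`` is the time of the bandpassed minimum inside each event
    (earliest minimum on ties), the alignment point for averaging.
    """
    if fs_hz < 400.0:
        raise ConfigurationError(
            "sampling rate below 400 Hz: ripple band unresolvable")
    x = np.asarray(site_signal, dtype=float)
    if x.std() == 0.0:
        return IntervalSet.from_arrays("ripple", [], [])
    bp = bandpass_ripple(x, fs_hz, band)
    nbin = int(round(rms_bin_ms * fs_hz / 1000.0))
    stride = max(1, nbin // 2)
    n_wins = 1 + (bp.size - nbin) // stride
    idx = np.arange(n_wins)[:, None] * stride + np.arange(nbin)[None, :]
    rms = np.sqrt(np.mean(bp[idx] ** 2, axis=1))
    starts, ends, thr = events_from_rms(rms, stride * 1000.0 / fs_hz,
                                        rms_bin_ms, onset_sd, boundary_sd,
                                        min_duration_ms, merge_gap_ms)
    peaks = []
    ms_per = 1000.0 / fs_hz
    for s, e in zip(starts, ends):
        i0, i1 = int(s / ms_per), max(int(e / ms_per) + 1, int(s / ms_per) + 1)
        i1 = min(i1, bp.size)
        peaks.append((i0 + int(np.argmin(bp[i0:i1]))) * ms_per)
    return IntervalSet.from_arrays("ripple", starts, ends, peaks,
                                   onset=thr[0], boundary=thr[1], band=band)


def events_from_rms(rms, stride_ms, bin_ms, onset_sd=3.0, boundary_sd=2.0,
                    min_duration_ms=20.0, merge_gap_ms=10.0):
    """Event extraction from an RMS series: onset above mean + 3 x SD,
    boundaries extended to mean + 2 x SD, events shorter than 20 ms
    discarded and neighbours closer than 10 ms merged.

    Returns ``(starts_ms, ends_ms, (onset_thr, boundary_thr))`` with event
    times at RMS bin centres.
    """
    rms = np.asarray(rms, dtype=float)
    sd = rms.std()
    if sd == 0.0:
        z = np.zeros(0)
        return z, z, (np.inf, np.inf)
    mu = rms.mean()
    si, ei = _threshold_epochs(rms, mu + onset_sd * sd)
    lo = mu + boundary_sd * sd
    starts, ends = [], []
    for s, e in zip(si, ei):
        while s > 0 and rms[s - 1] > lo:
            s -= 1
        while e < rms.size and rms[e] > lo:
            e += 1
        t0 = s * stride_ms + 0.5 * bin_ms
        t1 = (e - 1) * stride_ms + 0.5 * bin_ms
        if starts and t0 <= ends[-1]:
            ends[-1] = max(ends[-1], t1)
            continue
        starts.append(t0)
        ends.append(t1)
    starts, ends = merge_intervals(np.array(starts), np.array(ends),
                                   merge_gap_ms)
    keep = (ends - starts) >= min_duration_ms
    return starts[keep], ends[keep], (mu + onset_sd * sd, lo)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def band_psd(trace, fs_hz: float = 1000.0, state_mask=None,
             band=(100.0, 250.0), nperseg: int = 256):
    """Welch power spectral density of a trace, optionally restricted to
    concatenated state segments (e.g. UP states).

    Returns ``(freqs, psd, peak_freq_in_band)``.
    """
    x = np.asarray(trace, dtype=float)
    if state_mask is not None:
        m = np.asarray(state_mask, dtype=bool)
        if m.sum() == 0:
            raise ConfigurationError("state mask removes all data")
        x = x[m]
    min_len = int(4 * fs_hz / band[0])
    if x.size < min_len:
        raise ConfigurationError("trace shorter than 4 band periods")
    x = x - x.mean()
    f, p = sps.welch(x, fs=fs_hz, nperseg=min(nperseg, x.size))
    sel = (f >= band[0]) & (f <= band[1])
    peak = float(f[sel][np.argmax(p[sel])]) if sel.any() else float("nan")
    return f, p, peak
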