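"""Event detection: UP states, SO cycles, CA3 bursts, ripples, spectra."""

import numpy as np
import pytest

from swrnet.cells import ConfigurationError
from swrnet.events import (IntervalSet, band_psd, bandpass_ripple,
                           burst_participation, detect_ca3_bursts,
                           detect_ripples, detect_up_states,
                           extract_so_cycles, merge_intervals, so_frequency)


# ---------------------------------------------------------------------------
# UP states
# ---------------------------------------------------------------------------


def test_square_wave_up_states():
    """0/1 square wave with 600 ms half-period: one UP per cycle with
    boundaries at the transitions (+- one sample)."""
    fs = 1000.0
    cycle = np.concatenate([np.zeros(600), np.ones(600)])
    x = np.tile(cycle, 5)
    ups = detect_up_states(x, fs)
    assert len(ups) == 5
    for i, (s, e) in enumerate(zip(ups.starts, ups.ends)):
        assert s == pytest.approx(1200 * i + 600, abs=2.0)
        assert e == pytest.approx(1200 * i + 1200, abs=2.0)


def test_close_up_states_are_merged():
    """Two supra-threshold epochs 50 ms apart merge into one event."""
    x = np.zeros(3000)
    x[1000:1200] = 1.0
    x[1250:1450] = 1.0
    ups = detect_up_states(x, 1000.0)
    assert len(ups) == 1
    assert ups.starts[0] == pytest.approx(1000, abs=2)
    assert ups.ends[0] == pytest.approx(1450, abs=2)
    # 150 ms apart stays two events
    y = np.zeros(3000)
    y[1000:1200] = 1.0
    y[1350:1550] = 1.0
    assert len(detect_up_states(y, 1000.0)) == 2


def test_up_state_count_matches_scan_oracle_on_noise(rng):
    """White noise at a high threshold: epoch count equals a direct
    sample-scan oracle using the same threshold and merge rule."""
    x = np.abs(rng.normal(0.0, 1.0, 20000))
    ups = detect_up_states(x, 1000.0)
    thr = 0.45 * x.std()
    above = x > thr
    # scan oracle: count threshold epochs then apply the <100 ms merge
    starts, ends = [], []
    inside = False
    for i, a in enumerate(above):
        if a and not inside:
            starts.append(i)
            inside = True
        elif not a and inside:
            ends.append(i)
            inside = False
    if inside:
        ends.append(len(above))
    m_s, m_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - m_e[-1] < 100:
            m_e[-1] = e
        else:
            m_s.append(s)
            m_e.append(e)
    assert len(ups) == len(m_s)


def test_zero_variance_signal_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        ups = detect_up_states(np.ones(2000), 1000.0)
    assert len(ups) == 0


def test_detection_idempotence():
    """Re-detecting on the signal restricted to detected events returns the
    same events."""
    fs = 1000.0
    x = np.zeros(6000)
    for k in range(4):
        x[1000 + 1200 * k:1500 + 1200 * k] = 1.0
    ups = detect_up_states(x, fs)
    mask = ups.contains(np.arange(x.size))
    x2 = np.where(mask, x, 0.0)
    ups2 = detect_up_states(x2, fs)
    assert len(ups2) == len(ups)
    np.testing.assert_allclose(ups2.starts, ups.starts, atol=2.0)


def test_merge_is_associative(rng):
    """Order of pairwise merges does not change the final set."""
    starts = np.sort(rng.uniform(0, 10000, 40))
    ends = starts + rng.uniform(5, 120, 40)
    ends = np.minimum(ends, np.inf)
    # sequential merge of all at once
    s1, e1 = merge_intervals(starts, ends, 100.0)
    # merge first half, then second half, then concatenate and merge again
    s_a, e_a = merge_intervals(starts[:20], ends[:20], 100.0)
    s_b, e_b = merge_intervals(starts[20:], ends[20:], 100.0)
    s2, e2 = merge_intervals(np.concatenate([s_a, s_b]),
                             np.concatenate([e_a, e_b]), 100.0)
    np.testing.assert_allclose(s1, s2)
    np.testing.assert_allclose(e1, e2)


# ---------------------------------------------------------------------------
# SO cycles
# ---------------------------------------------------------------------------


def test_three_up_states_give_two_cycles():
    ups = IntervalSet.from_arrays("UP_state", [0, 1000, 2000],
                                  [400, 1400, 2400])
    cyc = extract_so_cycles(ups)
    assert len(cyc) == 2
    np.testing.assert_allclose(cyc.starts, [400, 1400])
    np.testing.assert_allclose(cyc.ends, [1400, 2400])


def test_periodic_cycles_have_constant_duration():
    starts = np.arange(0, 12000, 1200.0)
    ups = IntervalSet.from_arrays("UP_state", starts, starts + 500)
    cyc = extract_so_cycles(ups)
    np.testing.assert_allclose(cyc.durations, 1200.0)
    assert so_frequency(cyc) == pytest.approx(1000.0 / 1200.0)


def test_fewer_than_two_up_states_gives_empty():
    ups = IntervalSet.from_arrays("UP_state", [100], [400])
    assert len(extract_so_cycles(ups)) == 0


# ---------------------------------------------------------------------------
# CA3 bursts
# ---------------------------------------------------------------------------


def test_triangular_burst_boundaries():
    """A triangular rate bump crossing both thresholds: one burst, with
    boundaries where the rate drops below 1.2 x SD."""
    r = np.zeros(400)
    r[200:221] = np.concatenate([np.linspace(0, 30, 11),
                                 np.linspace(30, 0, 11)[1:]])
    b = detect_ca3_bursts(r, bin_ms=10.0)
    assert len(b) == 1
    lo = 1.2 * r.std()
    # oracle: first/last bins above the boundary threshold around the apex
    above = np.nonzero(r > lo)[0]
    assert b.starts[0] <= above[0] * 10.0
    assert b.ends[0] >= above[-1] * 10.0
    assert b.starts[0] >= (above[0] - 1) * 10.0
    assert b.ends[0] <= (above[-1] + 2) * 10.0


def test_flat_rate_no_bursts():
    assert len(detect_ca3_bursts(np.full(500, 3.0))) == 0


def test_burst_participation_counts_distinct_cells():
    bursts = IntervalSet.from_arrays("CA3_burst", [100.0], [200.0])
    times = np.array([110.0, 120.0, 130.0, 150.0, 500.0])
    cells = np.array([3, 3, 7, 9, 500])
    part = burst_participation(bursts, times, cells, 100)
    assert part[0] == pytest.approx(0.03)


# ---------------------------------------------------------------------------
# ripples
# ---------------------------------------------------------------------------


def test_pure_tone_burst_detected_once(rng):
    """A 50 ms 175 Hz tone at 10x noise SD yields exactly one ripple
    spanning the burst (+- one RMS bin)."""
    fs = 1000.0
    n = 20000
    noise = rng.normal(0.0, 1.0, n)
    x = noise.copy()
    t0 = 10000
    tt = np.arange(50)
    x[t0:t0 + 50] += 10.0 * np.sin(2 * np.pi * 175.0 * tt / fs)
    rip = detect_ripples(x, fs)
    assert len(rip) == 1
    assert rip.starts[0] == pytest.approx(t0, abs=15.0)
    assert rip.ends[0] == pytest.approx(t0 + 50, abs=15.0)
    assert t0 <= rip.peaks[0] <= t0 + 50


def test_short_supra_threshold_event_discarded():
    """A supra-threshold RMS excursion spanning only 15 ms is discarded
    (< 20 ms total duration), a 30 ms one is kept."""
    from swrnet.events import events_from_rms
    base = np.full(2000, 1.0)
    short = base.copy()
    short[1000:1003] = 12.0        # 3 windows -> 10 ms centre span
    s, e, _ = events_from_rms(short, 5.0, 10.0)
    assert len(s) == 0
    kept = base.copy()
    kept[1000:1006] = 12.0         # 6 windows -> 25 ms centre span
    s, e, _ = events_from_rms(kept, 5.0, 10.0)
    assert len(s) == 1
    assert (e[0] - s[0]) >= 20.0


def test_zero_signal_no_ripples():
    assert len(detect_ripples(np.zeros(5000), 1000.0)) == 0


def test_low_sampling_rate_rejected():
    with pytest.raises(ConfigurationError):
        detect_ripples(np.zeros(1000), 300.0)


def test_bandpass_preserves_inband_tone(rng):
    fs = 1000.0
    t = np.arange(4000) / fs
    x = np.sin(2 * np.pi * 175.0 * t) + np.sin(2 * np.pi * 10.0 * t)
    bp = bandpass_ripple(x, fs)
    # in-band power retained, out-of-band removed
    seg = slice(1000, 3000)
    assert np.std(bp[seg]) > 0.5
    slow = np.convolve(bp, np.ones(50) / 50, mode="same")
    assert np.std(slow[seg]) < 0.1


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def test_psd_peak_at_tone_frequency():
    fs = 1000.0
    t = np.arange(8000) / fs
    x = np.sin(2 * np.pi * 180.0 * t)
    _, _, peak = band_psd(x, fs)
    assert peak == pytest.approx(180.0, abs=1000.0 / 256 + 1)


def test_psd_white_noise_flat_in_ripple_band(rng):
    x = rng.normal(0, 1, 8000)
    f, p, _ = band_psd(x, 1000.0)
    sel = (f >= 150) & (f <= 200)
    assert p[sel].max() < 3.0 * np.median(p)


def test_psd_state_mask():
    fs = 1000.0
    t = np.arange(8000) / fs
    x = np.sin(2 * np.pi * 180.0 * t)
    mask = np.zeros(8000, dtype=bool)
    mask[:4000] = True
    _, _, peak = band_psd(x, fs, state_mask=mask)
    assert peak == pytest.approx(180.0, abs=1000.0 / 256 + 1)
    with pytest.raises(ConfigurationError):
        band_psd(x, fs, state_mask=np.zeros(8000, dtype=bool))
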