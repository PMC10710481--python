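"""Theta cycle detection and theta-sequence scoring."""

import numpy as np
import pandas as pd
import pytest

from replaykit import AnalysisConfig
from replaykit.behavior import linearize_and_speed
from replaykit.lfp import band_filter_hilbert
from replaykit.placefields import RateMapSet
from replaykit.session import LfpTrace, Session, Track, Unit
from replaykit.theta import (DecodedCycle, ThetaCycle, _alternating_extrema,
                             average_theta_sequences, center_posterior,
                             decode_theta_windows, detect_theta_cycles,
                             score_theta_significance)

FS = 1000.0
TRACK = Track(1, 300.0, (0.0, 0.0), (300.0, 0.0))


def _lin_ramp(speed=20.0, dur=10.0, start_x=40.0):
    t = np.arange(0, dur, 0.04)
    x = start_x + speed * t
    pos = pd.DataFrame({"time_s": t, "x_cm": x, "y_cm": 0.0})
    return linearize_and_speed(pos, TRACK)


def _theta_band(freq=8.0, dur=10.0, noise=0.0, rng=None):
    t = np.arange(0, dur, 1 / FS)
    x = 50 * np.sin(2 * np.pi * freq * t)
    if noise:
        x = x + rng.normal(0, noise, x.size)
    return band_filter_hilbert(LfpTrace(0, FS, x), (4.0, 12.0))


def test_pure_eight_hz_run_gives_regular_cycles():
    band = _theta_band()
    lin = _lin_ramp()
    cycles = detect_theta_cycles(band, lin, (0.0, 10.0))
    # ~80 cycles at 8 Hz; edge cycles near reward zones / filter edges drop
    assert 60 <= len(cycles) <= 80
    durs = np.array([c.duration_s for c in cycles])
    np.testing.assert_allclose(durs, 0.125, atol=0.005)
    assert all(c.direction == 1 for c in cycles)


def test_cycles_outside_duration_band_are_discarded():
    # ~140 oscillation periods at 14.3 Hz (70-ms cycles): all rejected; at
    # most a stray filter-edge artifact survives, itself inside the band
    cycles = detect_theta_cycles(_theta_band(freq=14.3), _lin_ramp(), (0.0, 10.0))
    assert len(cycles) <= 2
    assert all(0.08 <= c.duration_s <= 0.2 for c in cycles)
    # ~45 periods at 4.5 Hz (222-ms cycles): same
    cycles = detect_theta_cycles(_theta_band(freq=4.5), _lin_ramp(), (0.0, 10.0))
    assert len(cycles) <= 2
    assert all(0.08 <= c.duration_s <= 0.2 for c in cycles)


def test_slow_or_reward_zone_cycles_are_excluded():
    band = _theta_band()
    slow = _lin_ramp(speed=2.0)
    assert detect_theta_cycles(band, slow, (0.0, 10.0)) == []
    in_zone = _lin_ramp(speed=20.0, start_x=285.0)  # rides past the end zone
    cycles = detect_theta_cycles(band, in_zone, (0.0, 10.0))
    assert cycles == []


def _reference_extrema(x, threshold):
    """Brute-force alternation scan over all local extrema."""
    ext = []
    for i in range(1, x.size - 1):
        if x[i] >= x[i - 1] and x[i] >= x[i + 1] and abs(x[i]) >= threshold:
            ext.append((i, 1))
        elif x[i] <= x[i - 1] and x[i] <= x[i + 1] and abs(x[i]) >= threshold:
            ext.append((i, -1))
    out = []
    for i, kind in ext:
        if out and out[-1][1] == kind:
            j, _ = out[-1]
            if (kind == 1 and x[i] > x[j]) or (kind == -1 and x[i] < x[j]):
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    return out


def test_extrema_scan_matches_reference_on_noisy_signal(rng):
    band = _theta_band(noise=8.0, rng=rng)
    threshold = 0.25 * float(np.median(band.amplitude))
    got = _alternating_extrema(band.filtered, threshold)
    want = _reference_extrema(band.filtered, threshold)
    assert got == want


def _cycle_fixture(rng, n_units=15, n_bins=40, T=10, sweep=True, direction=1,
                   position_cm=41.0):
    """A decoded cycle built from a constructed count matrix and map."""
    centers = np.linspace(3, n_bins - 4, n_units)
    edges = np.arange(0, 2.0 * (n_bins + 1), 2.0)
    rates = {
        u: 15.0 * np.exp(-((np.arange(n_bins) - centers[u]) ** 2) / (2 * 2.0**2))
        for u in range(n_units)
    }
    lap_map = RateMapSet(1, edges, rates, np.ones(n_bins), smoothed=True)
    counts = np.zeros((n_units, T))
    for k in range(T):
        if sweep:
            u = int(k * n_units / T)
        else:
            u = int(rng.integers(0, n_units))
        counts[u, k] = 2
    from replaykit.decoder import decode

    post = decode(counts, [lap_map], list(range(n_units)), tau=0.01)
    cyc = ThetaCycle(0.0, 0.1, position_cm=position_cm, direction=direction,
                     speed_cms=20.0, lap=0, n_active_units=n_units)
    return DecodedCycle(cyc, post.probs, lap_map.bin_centers, counts,
                        list(range(n_units)), lap_map)


def test_perfect_sweep_is_significant_and_noise_cycles_rarely_are(rng):
    dc = _cycle_fixture(rng, sweep=True)
    r, p_vals, sig = score_theta_significance(None, dc, AnalysisConfig(),
                                              np.random.default_rng(0), n_shuffles=300)
    assert sig and r > 0.5
    n_sig = 0
    n = 60
    for k in range(n):
        dc = _cycle_fixture(np.random.default_rng(k), sweep=False)
        _, _, s = score_theta_significance(None, dc, AnalysisConfig(),
                                           np.random.default_rng(1000 + k),
                                           n_shuffles=150)
        n_sig += int(s)
    assert n_sig / n <= 0.125  # <= 5% expected; bound allows binomial noise


def test_cycle_with_single_active_unit_is_excluded():
    rng = np.random.default_rng(0)
    n_bins = 40
    edges = np.arange(0, 2.0 * (n_bins + 1), 2.0)
    rates = {0: np.ones(n_bins), 1: np.ones(n_bins)}
    lap_map = RateMapSet(1, edges, rates, np.ones(n_bins), smoothed=True)
    units = [Unit(0, np.array([10.02, 10.04, 10.06]), 700.0, 1.0),
             Unit(1, np.array([50.0]), 700.0, 1.0)]
    pos = pd.DataFrame({"time_s": np.arange(0, 60, 0.04), "x_cm": 40.0, "y_cm": 0.0})
    epochs = pd.DataFrame({"label": ["RUN1_T1"], "start_s": [0.0], "end_s": [60.0]})
    session = Session(units, pos, [], epochs, {1: TRACK}).validate()
    cycles = [ThetaCycle(10.0, 10.12, 40.0, 1, 20.0)]
    laps = pd.DataFrame({"lap": [0], "start_s": [0.0], "end_s": [60.0],
                         "track": [1], "epoch": ["RUN1_T1"]})
    decoded = decode_theta_windows(session, cycles, laps, {(0, 1): lap_map}, [0, 1])
    assert decoded == []


def test_identical_centered_posteriors_average_to_themselves(rng):
    dc = _cycle_fixture(rng, sweep=True)
    res = average_theta_sequences([dc, dc], score=False)
    np.testing.assert_allclose(res.average_posterior,
                               center_posterior(dc)[:, :res.average_posterior.shape[1]])
    assert res.centered_axis_cm[0] == -40.0 and res.centered_axis_cm[-1] == 40.0


def test_opposite_directions_are_mirrored_before_averaging(rng):
    fwd = _cycle_fixture(rng, sweep=True, direction=1)
    rev = _cycle_fixture(rng, sweep=True, direction=-1)
    rev.posterior = fwd.posterior[::-1].copy()  # same sweep seen inbound
    a = center_posterior(fwd)
    # the mirrored inbound posterior re-registers to the same centered frame
    # (mirror of a bin center across the track midline is again a bin center)
    rev.cycle.position_cm = (rev.bin_centers[0] + rev.bin_centers[-1]
                             - fwd.cycle.position_cm)
    b = center_posterior(rev)
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_theta_sequence_counts_increase_with_experience(small_session, analysis_cfg):
    """More decodable cycles accumulate on the many-lap track (RUN1 T1 vs T2)."""
    from replaykit.behavior import session_behavior
    from replaykit.lfp import select_channels
    from replaykit.placefields import classify_units, place_cells
    from replaykit.theta import lap_directional_maps

    session, _ = small_session
    summaries, lap_table, lins = session_behavior(session, analysis_cfg)
    roster = classify_units(session, lins, analysis_cfg)
    ch = select_channels(session.lfp, analysis_cfg)
    band = band_filter_hilbert(
        next(tr for tr in session.lfp if tr.channel_id == ch["theta"]),
        analysis_cfg.theta_band_hz)
    counts = {}
    for label, tid in (("RUN1_T1", 1), ("RUN1_T2", 2)):
        cycles = detect_theta_cycles(band, lins[tid], session.epoch_bounds(label),
                                     analysis_cfg)
        uids = place_cells(roster, tid)
        laps = lap_table[lap_table["epoch"] == label]
        lmaps = lap_directional_maps(session, lins[tid], laps, uids, analysis_cfg)
        decoded = decode_theta_windows(session, cycles, laps, lmaps, uids, analysis_cfg)
        counts[label] = len(decoded)
    # 4 laps on T1 vs 2 on T2: decodable cycle counts scale with laps run
    assert counts["RUN1_T1"] > counts["RUN1_T2"]
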