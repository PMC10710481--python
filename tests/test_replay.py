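"""Replay scoring: weighted correlation, detection, shuffles, assignment."""

import numpy as np
import pandas as pd
import pytest

from replaykit import AnalysisConfig, weighted_correlation
from replaykit.lfp import SleepMask, band_filter_hilbert
from replaykit.placefields import RateMapSet
from replaykit.replay import (CandidateEvent, ReplayScore, TrackScore, assign_track,
                              classify_swr_by_selective_cells, detect_candidates,
                              label_state, score_counts, split_event)
from replaykit.session import LfpTrace, Session, Track, Unit


def brute_wcorr(prob):
    M, N = prob.shape
    s = prob.sum()
    mx = sum(prob[i, j] * i for i in range(M) for j in range(N)) / s
    mt = sum(prob[i, j] * j for i in range(M) for j in range(N)) / s
    cxt = sum(prob[i, j] * (i - mx) * (j - mt) for i in range(M) for j in range(N)) / s
    cxx = sum(prob[i, j] * (i - mx) ** 2 for i in range(M) for j in range(N)) / s
    ctt = sum(prob[i, j] * (j - mt) ** 2 for i in range(M) for j in range(N)) / s
    return cxt / np.sqrt(cxx * ctt)


@pytest.mark.parametrize(
    "prob,expected",
    [
        (np.eye(5), 1.0),
        (np.eye(5)[::-1], -1.0),
        (np.ones((4, 6)), 0.0),
    ],
    ids=["diagonal", "anti-diagonal", "uniform"],
)
def test_weighted_correlation_canonical_matrices(prob, expected):
    assert weighted_correlation(prob) == pytest.approx(expected, abs=1e-12)


def test_weighted_correlation_matches_brute_force_and_stays_bounded(rng):
    for _ in range(100):
        p = rng.random((rng.integers(2, 8), rng.integers(2, 8)))
        r = weighted_correlation(p)
        assert abs(r - brute_wcorr(p)) < 1e-12
        assert -1.0 <= r <= 1.0


def test_weighted_correlation_degenerate_mass_is_nan():
    p = np.zeros((5, 4))
    p[2, :] = 1.0  # zero variance in position
    assert np.isnan(weighted_correlation(p))


# --------------------------------------------------------------------------
# candidate detection on constructed sessions


def _burst_session(burst_times, gap_session=60.0, n_units=12, seed=0,
                   burst_spikes=8, ripple=True, base_rate=1.0):
    """Quiet baseline with population bursts at given (start, dur) times."""
    rng = np.random.default_rng(seed)
    units = []
    for uid in range(n_units):
        st = [np.sort(rng.uniform(0, gap_session, rng.poisson(base_rate * gap_session)))]
        for s, d in burst_times:
            st.append(np.sort(s + rng.random(burst_spikes) * d))
        units.append(Unit(uid, np.sort(np.concatenate(st)), 700.0, 1.0))
    fs = 1000.0
    t = np.arange(0, gap_session, 1 / fs)
    trace = rng.normal(0, 5.0, t.size)
    if ripple:
        for s, d in burst_times:
            sel = (t >= s) & (t < s + d)
            trace[sel] += 60 * np.sin(2 * np.pi * 180 * t[sel])
    pos = pd.DataFrame({"time_s": np.arange(0, gap_session, 0.04),
                        "x_cm": 0.0, "y_cm": 0.0})
    epochs = pd.DataFrame({"label": ["POST1"], "start_s": [0.0], "end_s": [gap_session]})
    session = Session(units, pos, [LfpTrace(0, fs, trace)], epochs,
                      {1: Track(1, 200.0, (0.0, 0.0), (200.0, 0.0))}).validate()
    band = band_filter_hilbert(session.lfp[0], (125.0, 300.0))
    speed_t = pos["time_s"].to_numpy()
    return session, band, speed_t, np.zeros(speed_t.size)


def test_flat_mua_yields_no_events():
    session, band, st, sp = _burst_session([])
    events = detect_candidates(session, band, st, sp, (0.0, 60.0))
    assert events == []


def test_two_bursts_forty_ms_apart_are_combined():
    session, band, st, sp = _burst_session([(10.0, 0.08), (10.2, 0.08)])
    # gap between burst cores is 120 ms; boundary extension to z=0 brings the
    # flanks within the 50-ms merge window only for truly adjacent bursts
    session2, band2, st2, sp2 = _burst_session([(10.0, 0.08), (10.12, 0.08)])
    merged = detect_candidates(session2, band2, st2, sp2, (0.0, 60.0))
    assert len(merged) == 1
    ev = merged[0]
    assert ev.start_s < 10.0 + 0.02 and ev.end_s > 10.12
    assert len(ev.participating_units) == 12
    assert 0.1 <= ev.duration_s <= 0.75


def test_event_during_movement_is_excluded():
    session, band, st, sp = _burst_session([(10.0, 0.2)])
    events = detect_candidates(session, band, st, np.full(st.size, 10.0), (0.0, 60.0))
    assert events == []


def test_event_without_ripple_power_is_excluded():
    session, band, st, sp = _burst_session([(10.0, 0.2)], ripple=False)
    assert detect_candidates(session, band, st, sp, (0.0, 60.0)) == []


def test_detected_events_respect_candidate_invariants(small_session, analysis_cfg):
    from replaykit.behavior import linearize_session
    from replaykit.lfp import select_channels

    session, _ = small_session
    _, lins = linearize_session(session, analysis_cfg)
    lin = lins[1]
    ch = select_channels(session.lfp, analysis_cfg)
    band = band_filter_hilbert(
        next(tr for tr in session.lfp if tr.channel_id == ch["ripple"]),
        analysis_cfg.ripple_band_hz)
    events = detect_candidates(session, band, lin.time_s, lin.speed_cms,
                               session.epoch_bounds("POST1"), "POST1", analysis_cfg)
    assert len(events) > 5
    for ev in events:
        assert 0.1 <= ev.duration_s <= 0.75
        assert len(ev.participating_units) >= 5
        assert ev.peak_mua_z > 3 and ev.peak_ripple_z > 3
    gaps = np.diff([ev.start_s for ev in events])
    ends = np.array([ev.end_s for ev in events[:-1]])
    starts = np.array([ev.start_s for ev in events[1:]])
    assert np.all(starts - ends >= 0.05)


# --------------------------------------------------------------------------
# significance scoring on constructed count matrices


def _gaussian_maps(rng, n_units=20, n_bins=20, track_id=1, peak=12.0):
    centers = rng.uniform(0, n_bins - 1, n_units)
    edges = np.arange(0, 10 * (n_bins + 1), 10.0)
    rates = {
        u: peak * np.exp(-((np.arange(n_bins) - centers[u]) ** 2) / (2 * 1.5**2))
        for u in range(n_units)
    }
    return RateMapSet(track_id, edges, rates, np.ones(n_bins)), centers


def test_sequence_event_is_significant_and_noise_event_is_not(rng):
    maps1, centers = _gaussian_maps(rng, track_id=1)
    maps2, _ = _gaussian_maps(rng, track_id=2)
    uids = list(range(20))
    order = np.argsort(centers)
    T = 10
    counts = np.zeros((20, T))
    for k, u in enumerate(order):  # orderly sweep across the track
        counts[u, int(k * T / 20)] += 2
    cfg = AnalysisConfig(seed=0)
    scores = score_counts(counts, [maps1, maps2], uids, cfg,
                          np.random.default_rng(1), n_shuffles=300)
    assert scores[1].significant
    assert scores[1].bias > 0.6
    noise = rng.poisson(0.5, (20, T)).astype(float)
    nscores = score_counts(noise, [maps1, maps2], uids, cfg,
                           np.random.default_rng(2), n_shuffles=300)
    assert not (nscores[1].significant and nscores[2].significant)


def test_half_event_scoring_at_stricter_alpha(rng):
    """A clean sequence confined to the first half passes at alpha = 0.025."""
    maps1, centers = _gaussian_maps(rng, track_id=1)
    maps2, _ = _gaussian_maps(rng, track_id=2)
    order = np.argsort(centers)
    counts = np.zeros((20, 6))
    for k, u in enumerate(order):
        counts[u, int(k * 6 / 20)] += 2
    cfg = AnalysisConfig(seed=0)
    scores = score_counts(counts, [maps1, maps2], list(range(20)), cfg,
                          np.random.default_rng(3), alpha=0.025, n_shuffles=500)
    assert scores[1].significant


def _mk_score(sig1, sig2, bias1):
    ev = CandidateEvent(0.0, 0.2, 5.0, 5.0, set(range(6)), "POST1")
    per = {
        1: TrackScore(0.8, (0.01, 0.01, 0.01) if sig1 else (0.5,) * 3, sig1, bias1),
        2: TrackScore(0.5, (0.01, 0.01, 0.01) if sig2 else (0.5,) * 3, sig2, 1 - bias1),
    }
    return ReplayScore(ev, per, None, False)


def test_track_assignment_bias_rules():
    assert assign_track(_mk_score(True, False, 1.0)).assigned_track == 1
    sc = assign_track(_mk_score(True, True, 0.55))
    assert sc.assigned_track is None and sc.discarded
    assert assign_track(_mk_score(True, False, 0.61)).assigned_track == 1
    sc = assign_track(_mk_score(False, False, 0.9))
    assert sc.assigned_track is None and not sc.discarded


# --------------------------------------------------------------------------
# splitting and state labels


def test_split_at_center_when_middle_third_is_flat():
    # spikes only in the outer thirds -> flat (empty) MUA in the middle third
    session, _, _, _ = _burst_session([(10.0, 0.1), (10.35, 0.1)], burst_spikes=10,
                                      base_rate=0.0)
    ev = CandidateEvent(9.98, 10.47, 5.0, 5.0, set(range(12)), "POST1")
    halves = split_event(session, ev)
    assert len(halves) == 2
    mid = (9.98 + 10.47) / 2
    assert halves[0].end_s == pytest.approx(mid, abs=0.05)


def test_split_midpoint_tracks_mua_minimum():
    session, _, _, _ = _burst_session([(10.0, 0.12), (10.3, 0.25)], burst_spikes=12)
    ev = CandidateEvent(9.99, 10.56, 5.0, 5.0, set(range(12)), "POST1")
    halves = split_event(session, ev)
    assert len(halves) == 2
    # the MUA minimum sits in the silent stretch inside the middle third
    assert 10.12 <= halves[0].end_s <= 10.33


def test_no_split_when_halves_violate_duration():
    session, _, _, _ = _burst_session([(10.0, 0.15)])
    ev = CandidateEvent(10.0, 10.15, 5.0, 5.0, set(range(12)), "POST1")
    assert split_event(session, ev) == []


def _sleep_mask(flags, bin_s=60.0):
    n = len(flags)
    return SleepMask(pd.DataFrame({
        "bin_start_s": np.arange(n) * bin_s,
        "bin_end_s": np.arange(1, n + 1) * bin_s,
        "speed_ok": flags, "mua_ok": flags, "sleep": flags,
        "cum_sleep_s": np.cumsum(np.asarray(flags) * bin_s),
    }), bin_s)


def test_state_labels():
    mask = _sleep_mask([False, True])
    sc = _mk_score(True, False, 0.9)
    sc.assigned_track = 1
    sc.event.start_s, sc.event.end_s = 70.0, 70.2   # inside sleep bin
    assert label_state(sc, "POST1", None, mask) == "sleep"
    sc.event.start_s, sc.event.end_s = 10.0, 10.2   # awake bin
    assert label_state(sc, "POST1", None, mask) == "rest"
    assert label_state(sc, "RUN1_T1", 1, None) == "awake-local"
    assert label_state(sc, "RUN1_T2", 2, None) == "awake-remote"
    sc.assigned_track = None
    with pytest.raises(ValueError):
        label_state(sc, "POST1", None, mask)


# --------------------------------------------------------------------------
# decoding-free classification


def _cand(active):
    return CandidateEvent(0.0, 0.2, 5.0, 5.0, set(active), "POST1")


def test_selective_cell_classification_margin():
    selective = {"t1_only": list(range(10)), "t2_only": list(range(10, 20)), "dual": []}
    only_t1 = _cand(range(5))                      # 0.5 vs 0.0
    near_tie = _cand(list(range(5)) + list(range(10, 14)))  # 0.5 vs 0.4
    labels = classify_swr_by_selective_cells([only_t1, near_tie], selective)
    assert labels == [1, None]


def test_synthetic_single_track_events_classified_correctly(rng):
    selective = {"t1_only": list(range(12)), "t2_only": list(range(12, 24)), "dual": []}
    events, want = [], []
    for _ in range(40):
        tid = int(rng.random() < 0.5) + 1
        pool = selective["t1_only"] if tid == 1 else selective["t2_only"]
        events.append(_cand(rng.choice(pool, size=7, replace=False)))
        want.append(tid)
    labels = classify_swr_by_selective_cells(events, selective)
    correct = sum(1 for l, w in zip(labels, want) if l == w)
    assert correct / len(want) >= 0.9
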