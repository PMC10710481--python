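"""Session metrics, regressions, and paired comparisons."""

import numpy as np
import pandas as pd
import pytest

from replaykit import (compare_tracks, compute_session_metrics, cumulative_bias_trace,
                       per_cell_replay_regression, regress_mixed, regress_simple,
                       simulate_metrics_batch)
from replaykit.behavior import BehaviorSummary
from replaykit.lfp import SleepMask


def _mask(flags, start=0.0, bin_s=60.0):
    n = len(flags)
    return SleepMask(pd.DataFrame({
        "bin_start_s": start + np.arange(n) * bin_s,
        "bin_end_s": start + np.arange(1, n + 1) * bin_s,
        "speed_ok": flags, "mua_ok": flags, "sleep": flags,
        "cum_sleep_s": np.cumsum(np.asarray(flags, float) * bin_s),
    }), bin_s)


def _events(times_tracks_states, epoch="POST1"):
    rows = [{"start_s": t, "end_s": t + 0.2, "epoch": epoch, "track": trk,
             "state": st} for t, trk, st in times_tracks_states]
    return pd.DataFrame(rows)


def _summaries():
    return [
        BehaviorSummary(1, "RUN1_T1", 16, 300.0, 300.0, 30.0, 600.0),
        BehaviorSummary(2, "RUN1_T2", 4, 80.0, 70.0, 30.0, 150.0),
        BehaviorSummary(1, "RUN2_T1", 20, 400.0, 500.0, 30.0, 900.0),
        BehaviorSummary(2, "RUN2_T2", 20, 400.0, 500.0, 30.0, 900.0),
    ]


def test_sleep_replay_rate_is_count_over_window():
    # 54 track-1 sleep events inside 30 min of cumulative sleep -> 0.03 events/s
    flags = [True] * 30
    mask = _mask(flags)
    times = np.linspace(5, 1795, 54)
    ev = _events([(t, 1, "sleep") for t in times])
    metrics = compute_session_metrics(ev, {"POST1": mask, "POST2": _mask([True])},
                                      _summaries())
    row = metrics.per_track.query("exposure == 1 and track == 1").iloc[0]
    assert row["sleep_replay_rate"] == pytest.approx(54 / 1800)
    assert not row["partial_sleep_window"]
    row2 = metrics.per_track.query("exposure == 1 and track == 2").iloc[0]
    assert row2["sleep_replay_rate"] == 0.0


def test_partial_sleep_window_is_flagged_and_uses_available_time():
    mask = _mask([True] * 10)  # only 10 min of sleep
    ev = _events([(t, 1, "sleep") for t in np.linspace(5, 595, 12)])
    metrics = compute_session_metrics(ev, {"POST1": mask}, _summaries())
    row = metrics.per_track.query("exposure == 1 and track == 1").iloc[0]
    assert row["partial_sleep_window"]
    assert row["sleep_replay_rate"] == pytest.approx(12 / 600)


def test_cumulative_bias_final_value_equals_count_difference():
    flags = [True, False, True, True]
    mask = _mask(flags)
    ev = _events([(10, 1, "sleep"), (130, 1, "sleep"), (150, 2, "sleep"),
                  (200, 1, "sleep"), (70, 1, "rest")])
    trace = cumulative_bias_trace(ev, mask)
    sleep_ev = ev[ev["state"] == "sleep"]
    assert trace["bias"].iloc[-1] == ((sleep_ev["track"] == 1).sum()
                                      - (sleep_ev["track"] == 2).sum())
    assert (np.diff(trace["cum_sleep_s"]) == 60.0).all()


def test_regress_simple_exact_line_and_degenerate_inputs(rng):
    x = np.arange(10, dtype=float)
    rep = regress_simple(x, 2 * x + 1)
    assert rep.r_squared == pytest.approx(1.0)
    assert rep.p_value < 1e-10
    with pytest.raises(ValueError, match="zero variance"):
        regress_simple(np.full(8, 3.0), rng.random(8))
    # independent y: R^2 near zero at large n
    x = rng.random(4000)
    rep = regress_simple(x, rng.random(4000))
    assert rep.r_squared < 0.01


def test_wilcoxon_paired_comparisons():
    same = np.arange(1.0, 11.0)
    stat, p = compare_tracks(same, same)
    assert p == 1.0
    # constant +1 shift: the smallest attainable p for n = 10
    t1 = same + 1
    _, p_shift = compare_tracks(t1, same)
    from scipy.stats import wilcoxon
    ref = wilcoxon(np.ones(10), alternative="two-sided", method="exact").pvalue
    assert p_shift == pytest.approx(ref)
    with pytest.raises(ValueError, match="equal length"):
        compare_tracks(same, same[:-1])


def test_wilcoxon_power_under_shift(rng):
    """Power >= 0.8 for a 1-SD shift with 19 paired sessions."""
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        base = rng.normal(0, 1, 19)
        _, p = compare_tracks(base + 1.0, base + rng.normal(0, 1, 19) * 0.5)
        hits += p < 0.05
    assert hits / n_rep >= 0.8


def test_mixed_model_recovers_single_true_predictor():
    df = simulate_metrics_batch(seed=4, n_animals=4, n_sessions=10, beta_awake_n=0.6)
    rep = regress_mixed(df, "sleep_replay_rate",
                        ["awake_replay_rate", "n_awake_replay",
                         "n_theta_sequences", "time_on_track_s"])
    sig = set(rep.significant_terms())
    assert "n_awake_replay" in sig
    assert rep.coefficients.set_index("term").loc["n_awake_replay", "beta"] > 0.3
    coef = rep.coefficients.set_index("term")
    assert (coef["ci_low"] <= coef["beta"]).all() and (coef["beta"] <= coef["ci_high"]).all()


def test_mixed_model_constant_response_gives_null_betas():
    df = simulate_metrics_batch(seed=1, n_animals=3, n_sessions=4)
    df["sleep_replay_rate"] = 1.0
    rep = regress_mixed(df, "sleep_replay_rate", ["n_awake_replay", "time_on_track_s"])
    betas = rep.coefficients.set_index("term")["beta"]
    assert abs(betas["n_awake_replay"]) < 1e-6


def test_mixed_model_permuted_response_has_no_signal(rng):
    df = simulate_metrics_batch(seed=9, n_animals=4, n_sessions=6)
    false_hits = 0
    n_rep = 25
    for _ in range(n_rep):
        shuffled = df.copy()
        shuffled["sleep_replay_rate"] = rng.permutation(
            shuffled["sleep_replay_rate"].to_numpy())
        rep = regress_mixed(shuffled, "sleep_replay_rate",
                            ["n_awake_replay", "n_theta_sequences"])
        terms = [t for t in rep.significant_terms() if t != "intercept"]
        false_hits += bool(terms)
    assert false_hits / n_rep <= 0.25


def test_per_cell_regression_proportional_and_skip():
    cells = pd.DataFrame({"awake_diff": np.arange(8, dtype=float)})
    cells["sleep_diff"] = 0.02 * cells["awake_diff"]
    rep = per_cell_replay_regression(cells)
    assert rep.r_squared == pytest.approx(1.0)
    assert per_cell_replay_regression(cells.head(3)) is None


def test_per_cell_regression_shuffled_pairing_has_no_slope(rng):
    awake = rng.normal(0, 3, 400)
    sleep = 0.02 * awake + rng.normal(0, 0.01, 400)
    cells = pd.DataFrame({"awake_diff": awake,
                          "sleep_diff": rng.permutation(sleep)})
    rep = per_cell_replay_regression(cells)
    assert rep.r_squared < 0.03
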