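"""Session-level quantities and the regression layer.

Sleep replay rate is the number of a track's sleep replay events in the
first 30 min of cumulative putative sleep divided by 30 min; awake local
replay rate divides the count of local events by the time spent immobile
on the track. The cumulative replay bias is the running difference in
event counts (track 1 minus track 2) against cumulative sleep time.

Simple regressions are ordinary least squares; the mixed-effect layer
fits a random-intercept (animal) linear model on z-scored variables so
standardized betas are comparable, with Wald 95% confidence intervals; a
fixed effect is called significant when its interval excludes zero.
Track pairs are compared with the two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import AnalysisConfig
from .lfp import SleepMask


# --------------------------------------------------------------------------
# session metrics


@dataclass
class SessionMetrics:
    per_track: pd.DataFrame       # one row per (exposure, track)
    bias_traces: dict[str, pd.DataFrame]   # POST epoch -> cumulative bias trace
    decay_slopes: dict[tuple[str, int], float]


def _events_in_intervals(ev: pd.DataFrame, intervals) -> pd.DataFrame:
    if ev.empty or not intervals:
        return ev.iloc[0:0]
    mid = (ev["start_s"] + ev["end_s"]) / 2
    mask = np.zeros(len(ev), dtype=bool)
    for a, b in intervals:
        mask |= (mid >= a) & (mid < b)
    return ev[mask]


def cumulative_bias_trace(events: pd.DataFrame, sleep_mask: SleepMask) -> pd.DataFrame:
    """Cumulative (track 1 - track 2) sleep-replay count per sleep minute."""
    rows = []
    c1 = c2 = 0
    sleep_bins = sleep_mask.bins[sleep_mask.bins["sleep"]]
    ev = events[events["state"] == "sleep"]
    mid = (ev["start_s"] + ev["end_s"]) / 2 if not ev.empty else pd.Series(dtype=float)
    cum = 0.0
    for _, b in sleep_bins.iterrows():
        cum += sleep_mask.bin_s
        if not ev.empty:
            inside = (mid >= b["bin_start_s"]) & (mid < b["bin_end_s"])
            c1 += int(((ev["track"] == 1) & inside).sum())
            c2 += int(((ev["track"] == 2) & inside).sum())
        rows.append({"cum_sleep_s": cum, "bias": c1 - c2, "n_t1": c1, "n_t2": c2})
    return pd.DataFrame(rows)


def replay_decay_slope(events: pd.DataFrame, sleep_mask: SleepMask, track: int,
                       bin_s: float = 600.0) -> float:
    """OLS slope of sleep-replay rate per 10-min cumulative-sleep bin."""
    iv = sleep_mask.sleep_intervals()
    ev = events[(events["state"] == "sleep") & (events["track"] == track)]
    mids = ((ev["start_s"] + ev["end_s"]) / 2).to_numpy() if not ev.empty else np.empty(0)
    # map event times to cumulative sleep time
    cum_edges, acc = [], 0.0
    ev_cum = []
    for a, b in iv:
        for m in mids:
            if a <= m < b:
                ev_cum.append(acc + (m - a))
        acc += b - a
    if acc < 2 * bin_s:
        return np.nan
    edges = np.arange(0.0, acc + 1e-9, bin_s)
    if edges.size < 3:
        return np.nan
    counts = np.histogram(ev_cum, bins=edges)[0]
    rates = counts / bin_s
    centers = edges[:-1] + bin_s / 2
    if rates.std() == 0:
        return 0.0
    return float(np.polyfit(centers, rates, 1)[0])


def compute_session_metrics(
    events: pd.DataFrame,
    sleep_masks: dict[str, SleepMask],
    behavior_summaries: list,
    theta_counts: dict[str, tuple[int, int]] | None = None,
    candidate_counts: dict[str, int] | None = None,
    config: AnalysisConfig | None = None,
) -> SessionMetrics:
    """Assemble per-track, per-exposure headline quantities.

    ``theta_counts`` maps run-epoch label to (n significant sequences,
    n decoded cycles); ``candidate_counts`` maps run-epoch label to the
    number of candidate SWR events. Sleep rates use the first 30 min of
    cumulative sleep; when less is attained the rate uses the available
    time and the row is flagged ``partial_sleep_window``.
    """
    config = config or AnalysisConfig()
    theta_counts = theta_counts or {}
    candidate_counts = candidate_counts or {}
    behav = {s.epoch_label: s for s in behavior_summaries}
    rows = []
    post_of_exposure = {1: "POST1", 2: "POST2"}
    for exposure, run_labels in ((1, ["RUN1_T1", "RUN1_T2"]), (2, ["RUN2_T1", "RUN2_T2"])):
        post = post_of_exposure[exposure]
        mask = sleep_masks.get(post)
        window, attained = (mask.first_cumulative_window(config.sleep_window_s)
                            if mask else ([], 0.0))
        for label in run_labels:
            if label not in behav:
                continue
            track = behav[label].track_id
            post_ev = events[events["epoch"] == post] if not events.empty else events
            sleep_ev = _events_in_intervals(
                post_ev[(post_ev["state"] == "sleep") & (post_ev["track"] == track)]
                if not post_ev.empty else post_ev, window)
            sleep_rate = len(sleep_ev) / attained if attained > 0 else np.nan
            rest_ev = post_ev[(post_ev["state"] == "rest") & (post_ev["track"] == track)] \
                if not post_ev.empty else post_ev
            rest_time = (mask.bins.shape[0] * mask.bin_s - mask.total_sleep_s) if mask else np.nan
            rest_rate = len(rest_ev) / rest_time if mask and rest_time > 0 else np.nan
            run_ev = events[events["epoch"] == label] if not events.empty else events
            local = run_ev[(run_ev["state"] == "awake-local")] if not run_ev.empty else run_ev
            immobile = behav[label].time_immobile_s
            n_sig, n_cyc = theta_counts.get(label, (np.nan, np.nan))
            n_cand = candidate_counts.get(label, np.nan)
            rows.append({
                "exposure": exposure, "track": track, "run_epoch": label, "post_epoch": post,
                "sleep_replay_rate": sleep_rate, "n_sleep_replay": len(sleep_ev),
                "rest_replay_rate": rest_rate, "n_rest_replay": len(rest_ev),
                "awake_replay_rate": len(local) / immobile if immobile > 0 else np.nan,
                "n_awake_replay": len(local),
                "n_theta_sequences": n_sig, "n_theta_cycles": n_cyc,
                "n_awake_swr": n_cand,
                "awake_swr_rate": n_cand / immobile if immobile > 0 else np.nan,
                "time_on_track_s": behav[label].epoch_duration_s,
                "time_immobile_s": immobile,
                "partial_sleep_window": attained < config.sleep_window_s - 1e-9,
            })
    bias_traces = {}
    decay = {}
    for post in ("POST1", "POST2"):
        if post in sleep_masks and not events.empty:
            pev = events[events["epoch"] == post]
            bias_traces[post] = cumulative_bias_trace(pev, sleep_masks[post])
            for track in (1, 2):
                decay[(post, track)] = replay_decay_slope(pev, sleep_masks[post], track)
    return SessionMetrics(pd.DataFrame(rows), bias_traces, decay)


# --------------------------------------------------------------------------
# regression layer


@dataclass
class RegressionReport:
    model: str
    n: int
    r_squared: float
    p_value: float
    coefficients: pd.DataFrame   # term, beta, ci_low, ci_high, significant
    group: str | None = None

    def significant_terms(self) -> list[str]:
        c = self.coefficients
        return c.loc[c["significant"], "term"].tolist()


def regress_simple(x: np.ndarray, y: np.ndarray, name: str = "x") -> RegressionReport:
    """Ordinary least squares of y on x with R^2 and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame({
        "term": ["intercept", name],
        "beta": fit.params,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
    })
    coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)
    return RegressionReport("ols", int(x.size), float(fit.rsquared),
                            float(fit.pvalues[1]), coef)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def regress_mixed(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str = "animal",
) -> RegressionReport:
    """Random-intercept linear mixed model on z-scored variables.

    All variables are standardized so fixed-effect betas are comparable;
    95% Wald confidence intervals come from the fit; a term is
    significant when its interval excludes zero. Singular fits are
    reported as-is (statsmodels emits a convergence warning and the
    intervals widen accordingly).
    """
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 groups")
    z = pd.DataFrame({c: _zscore(data[c].to_numpy(float)) for c in [response] + fixed})
    k = len(fixed)
    if data[response].to_numpy(float).std() == 0:
        # degenerate response: every standardized beta is exactly zero
        coef = pd.DataFrame({"term": ["intercept"] + fixed, "beta": 0.0,
                             "ci_low": 0.0, "ci_high": 0.0, "significant": False})
        return RegressionReport("mixedlm", int(len(data)), np.nan, np.nan, coef, group)
    exog = sm.add_constant(z[fixed].to_numpy())
    model = sm.MixedLM(z[response].to_numpy(), exog, groups=data[group].to_numpy())
    fit = model.fit(reml=True)
    params = fit.params[: k + 1]
    bse = fit.bse[: k + 1]
    ci_low = params - 1.96 * bse
    ci_high = params + 1.96 * bse
    coef = pd.DataFrame({
        "term": ["intercept"] + fixed,
        "beta": params,
        "ci_low": ci_low,
        "ci_high": ci_high,
    })
    coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)
    try:
        r2 = float(1 - fit.resid.var() / z[response].var())
    except (np.linalg.LinAlgError, ValueError):  # singular random-effect fit
        r2 = np.nan
    return RegressionReport("mixedlm", int(len(data)), r2, np.nan, coef, group)


def per_cell_replay_regression(cell_table: pd.DataFrame) -> RegressionReport | None:
    """Per-session OLS of per-cell sleep-rate difference on awake-count difference.

    ``cell_table`` has one row per dual-track cell with columns
    ``awake_diff`` (track 1 - track 2 awake replay participation counts)
    and ``sleep_diff`` (track 1 - track 2 sleep replay participation
    rates). Sessions with fewer than 5 dual-track cells are skipped
    (returns None).
    """
    if len(cell_table) < 5:
        return None
    return regress_simple(cell_table["awake_diff"].to_numpy(),
                          cell_table["sleep_diff"].to_numpy(), name="awake_diff")


def compare_tracks(t1: np.ndarray, t2: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-session values."""
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.size != t2.size:
        raise ValueError("paired samples must have equal length")
    diff = t1 - t2
    if np.all(diff == 0):
        return 0.0, 1.0
    method = "exact" if t1.size < 5 else "auto"
    res = sps.wilcoxon(t1, t2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# metrics-level multi-session batches


def simulate_metrics_batch(
    seed: int,
    n_animals: int = 4,
    n_sessions: int = 10,
    beta_awake_n: float = 0.6,
    noise_sd: float = 0.5,
    animal_sd: float = 0.3,
) -> pd.DataFrame:
    """Synthetic multi-session metrics where awake-replay count is the only
    true driver of sleep-replay rate.

    Each row is one (animal, session, exposure, track) data point. Time
    on track varies across rows; theta-sequence count scales with time on
    track; awake replay count is rate x immobile time, so it correlates
    with the other covariates through time on track but is the only
    variable with a direct effect on sleep replay rate (standardized
    effect ``beta_awake_n``), on top of an animal-level random intercept.
    """
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = rng.normal(0.0, animal_sd, n_animals)
    for a in range(n_animals):
        for s in range(n_sessions):
            for exposure in (1, 2):
                for track in (1, 2):
                    time_on = rng.uniform(200.0, 1200.0)
                    awake_rate = rng.uniform(0.05, 0.15)
                    awake_n = awake_rate * 0.4 * time_on * rng.lognormal(0.0, 0.2)
                    theta_n = 2.0 * time_on * rng.lognormal(0.0, 0.2)
                    rows.append({
                        "animal": a, "session": s, "exposure": exposure, "track": track,
                        "time_on_track_s": time_on,
                        "awake_replay_rate": awake_rate,
                        "n_awake_replay": awake_n,
                        "n_theta_sequences": theta_n,
                    })
    df = pd.DataFrame(rows)
    z_awake = _zscore(df["n_awake_replay"].to_numpy())
    df["sleep_replay_rate"] = (
        beta_awake_n * z_awake
        + intercepts[df["animal"].to_numpy()]
        + rng.normal(0.0, noise_sd, len(df))
    )
    return df
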