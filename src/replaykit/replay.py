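"""Sharp-wave-ripple / MUA replay event detection and sequence scoring.

Candidate events are multi-unit activity bursts (1-ms binned, 5-ms
Gaussian smoothed, z > 3, burst core capped at 300 ms) whose boundaries
extend to the surrounding z = 0 crossings, that also carry ripple-band
power above z = 3; events within 50 ms are combined, events during
movement (> 5 cm/s) are excluded, and survivors need at least 5 active
units and a duration of 100-750 ms.

Each candidate is decoded in 20-ms windows and scored per track by the
weighted correlation of its posterior -- the correlation between decoded
position and time with each matrix cell weighted by its probability. The
score (absolute weighted correlation, so forward and reverse trajectories
score alike) is tested against three shuffle nulls: circular shift of
each unit's spike-count vector in time (pre-decoding), circular shift of
each ratemap in space (pre-decoding), and independent circular shifts of
each time bin's posterior in position. An event is significant for a
track only when it beats the 95th percentile of all three distributions;
multi-track events are resolved by the Bayesian bias score (one track's
posterior mass over the total), which must exceed 60%. Candidates that
fail may be split at the MUA minimum in their middle third and the halves
re-scored at alpha = 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .decoder import PosteriorMatrix, decode, count_spikes
from .lfp import BandSignal, SleepMask, mua_trace
from .placefields import RateMapSet
from .session import Session, Unit


# --------------------------------------------------------------------------
# weighted correlation (the sequence score)


def weighted_correlation(prob: np.ndarray) -> float:
    """Weighted correlation between position and time of a posterior matrix.

    ``prob[i, j]`` weights position bin i at time bin j; the weighted
    mean, covariance and correlation are taken over all (i, j) cells.
    Returns NaN when the weighted variance of either coordinate is zero.
    """
    r = _weighted_correlation_batch(np.asarray(prob, float)[None, ...])
    return float(r[0])


def _weighted_correlation_batch(probs: np.ndarray) -> np.ndarray:
    """Weighted correlation over the last two axes of ``probs`` (..., X, T)."""
    p = np.asarray(probs, float)
    M, N = p.shape[-2], p.shape[-1]
    x = np.arange(M, dtype=float)[:, None]
    t = np.arange(N, dtype=float)[None, :]
    w = p.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = (p * x).sum(axis=(-2, -1)) / w
        mt = (p * t).sum(axis=(-2, -1)) / w
        dx = x - mx[..., None, None]
        dt_ = t - mt[..., None, None]
        cxt = (p * dx * dt_).sum(axis=(-2, -1)) / w
        cxx = (p * dx * dx).sum(axis=(-2, -1)) / w
        ctt = (p * dt_ * dt_).sum(axis=(-2, -1)) / w
        r = cxt / np.sqrt(cxx * ctt)
    bad = ~np.isfinite(r)
    if np.any(bad):
        r = np.where(bad, np.nan, r)
    return r


# --------------------------------------------------------------------------
# candidate detection


@dataclass
class CandidateEvent:
    start_s: float
    end_s: float
    peak_mua_z: float
    peak_ripple_z: float
    participating_units: set[int]
    epoch: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _burst_intervals(t: np.ndarray, z: np.ndarray, z_peak: float, core_max_s: float):
    """Supra-threshold bursts extended to the flanking z = 0 crossings."""
    above = z > z_peak
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    dt = t[1] - t[0]
    nonpos = z <= 0
    out = []
    for i0, i1 in zip(starts, ends):
        if (i1 - i0) * dt > core_max_s:
            continue
        left = i0
        while left > 0 and not nonpos[left - 1]:
            left -= 1
        right = i1
        while right < z.size and not nonpos[right]:
            right += 1
        out.append((float(t[left]), float(t[min(right, z.size - 1)]), float(z[i0:i1].max())))
    return out


def _merge_within(intervals: list[tuple[float, float, float]], gap: float):
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e, pk in intervals[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], pk)
        else:
            merged.append([s, e, pk])
    return [tuple(m) for m in merged]


def zscore_ripple(ripple: BandSignal, epoch: tuple[float, float],
                  smooth_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-z-scored, moving-average-smoothed ripple-band amplitude."""
    t = ripple.times()
    sel = (t >= epoch[0]) & (t < epoch[1])
    amp = ripple.smoothed_amplitude(smooth_s)[sel]
    z = (amp - amp.mean()) / (amp.std() + 1e-12)
    return t[sel], z


def detect_candidates(
    session: Session,
    ripple: BandSignal,
    speed_times: np.ndarray,
    speed: np.ndarray,
    epoch: tuple[float, float],
    epoch_label: str = "",
    config: AnalysisConfig | None = None,
    units: list[Unit] | None = None,
) -> list[CandidateEvent]:
    """Detect candidate SWR/MUA events within one epoch."""
    config = config or AnalysisConfig()
    units = units if units is not None else session.units
    mua_t, mua_z = mua_trace(units, epoch[0], epoch[1],
                             config.mua_bin_s, config.mua_smooth_sd_s)
    bursts = _burst_intervals(mua_t, mua_z, config.mua_z_threshold, config.mua_burst_max_s)
    bursts = _merge_within(bursts, config.merge_gap_s)
    rip_t, rip_z = zscore_ripple(ripple, epoch, config.ripple_smooth_s)
    events = []
    for s, e, pk in bursts:
        i0, i1 = np.searchsorted(rip_t, [s, e])
        rz = float(rip_z[i0:i1].max()) if i1 > i0 else -np.inf
        if rz <= config.ripple_z_threshold:
            continue
        sp = speed[(speed_times >= s) & (speed_times < e)]
        if sp.size == 0:
            idx = np.clip(np.searchsorted(speed_times, (s + e) / 2), 0, speed.size - 1)
            sp = speed[idx:idx + 1]
        if sp.mean() > config.event_speed_max_cms:
            continue
        active = {u.unit_id for u in units if session.spikes_in(u, s, e).size > 0}
        if len(active) < config.event_min_units:
            continue
        dur = e - s
        if not (config.event_min_duration_s <= dur <= config.event_max_duration_s):
            continue
        events.append(CandidateEvent(s, e, pk, rz, active, epoch_label))
    return events


# --------------------------------------------------------------------------
# significance scoring


@dataclass
class TrackScore:
    r: float
    p_values: tuple[float, float, float]
    significant: bool
    bias: float


@dataclass
class ReplayScore:
    event: CandidateEvent
    per_track: dict[int, TrackScore]
    assigned_track: int | None
    discarded: bool
    split: bool = False
    state: str = ""

    @property
    def significant_tracks(self) -> list[int]:
        return [t for t, s in self.per_track.items() if s.significant]


def _decode_joint(counts, logF, fsum, tau):
    """Batch decode: counts (..., U, T), logF (..., U, X) -> (..., T, X)."""
    L = np.einsum("...ut,...ux->...tx", counts, logF) - tau * fsum[..., None, :]
    L -= L.max(axis=-1, keepdims=True)
    P = np.exp(L)
    P /= P.sum(axis=-1, keepdims=True)
    return P


def _shuffle_p(null: np.ndarray, obs: float) -> float:
    null = null[np.isfinite(null)]
    if null.size == 0:
        return 1.0
    return float((1 + np.sum(null >= obs)) / (1 + null.size))


def score_significance(
    session: Session,
    event: CandidateEvent,
    maps: list[RateMapSet],
    unit_ids: list[int],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    alpha: float | None = None,
    n_shuffles: int | None = None,
) -> ReplayScore:
    """Score one candidate event per track against the three shuffle nulls.

    The event is decoded in 20-ms windows with the unsmoothed decoding
    maps of both tracks jointly; each track's posterior sub-matrix is
    scored by |weighted correlation| and compared with the spike-train
    circular shift, place-field circular shift (both re-decoded), and
    per-time-bin posterior circular shift distributions.
    """
    config = config or AnalysisConfig()
    tau = config.decode_window_replay_s
    counts, _ = count_spikes(session, unit_ids, event.start_s, event.end_s, tau)
    min_bins = int(round(config.event_min_duration_s / tau))
    if counts.shape[1] < min_bins:
        return ReplayScore(event, {}, None, True)
    per_track = score_counts(counts, maps, unit_ids, config, rng,
                             alpha=alpha, n_shuffles=n_shuffles)
    return assign_track(ReplayScore(event, per_track, None, False), config)


def score_counts(
    counts: np.ndarray,
    maps: list[RateMapSet],
    unit_ids: list[int],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    alpha: float | None = None,
    n_shuffles: int | None = None,
) -> dict[int, "TrackScore"]:
    """Score a spike-count matrix (units x 20-ms windows) per track.

    Significance follows the conjunction rule: the observed |weighted
    correlation| must exceed the (1 - alpha) quantile of all three
    shuffle distributions. Permutation p-values (1 + #{null >= obs}) /
    (1 + S) are reported alongside.
    """
    config = config or AnalysisConfig()
    alpha = config.alpha if alpha is None else alpha
    S = config.n_shuffles if n_shuffles is None else n_shuffles
    rng = rng or np.random.default_rng(config.seed)
    tau = config.decode_window_replay_s
    counts = np.atleast_2d(np.asarray(counts, float))
    T = counts.shape[1]

    from .decoder import _stack_maps

    F, _, track_of_bin = _stack_maps(maps, unit_ids)
    logF = np.log(np.maximum(F, config.rate_floor_hz))
    fsum = F.sum(axis=0)
    U, X = F.shape
    P = _decode_joint(counts, logF, fsum, tau)   # (T, X)
    total = P.sum()

    # spike-train circular shift (pre-decoding)
    shift_t = rng.integers(1, T, size=(S, U)) if T > 1 else np.zeros((S, U), int)
    col_t = (np.arange(T)[None, None, :] + shift_t[:, :, None]) % T
    counts_shuf = np.take_along_axis(np.broadcast_to(counts, (S, U, T)), col_t, axis=2)
    P_spike = _decode_joint(counts_shuf, logF[None, ...], np.broadcast_to(fsum, (S, X)), tau)

    # place-field shift: roll each unit's map within its own track's bins
    Fs = np.broadcast_to(F, (S, U, X)).copy()
    for m in maps:
        sel = track_of_bin == m.track_id
        nb = int(sel.sum())
        shift_x = rng.integers(1, nb, size=(S, U)) if nb > 1 else np.zeros((S, U), int)
        idx = (np.arange(nb)[None, None, :] + shift_x[:, :, None]) % nb
        Fs[:, :, sel] = np.take_along_axis(Fs[:, :, sel], idx, axis=2)
    P_field = _decode_joint(counts[None, ...], np.log(np.maximum(Fs, config.rate_floor_hz)),
                            Fs.sum(axis=1), tau)

    per_track: dict[int, TrackScore] = {}
    for m in maps:
        sel = track_of_bin == m.track_id
        sub = P[:, sel].T                       # (Xt, T)
        r_signed = weighted_correlation(sub)
        obs = abs(r_signed)
        bias = float(P[:, sel].sum() / total)
        if np.isnan(obs):
            per_track[m.track_id] = TrackScore(np.nan, (1.0, 1.0, 1.0), False, bias)
            continue
        null_spike = np.abs(_weighted_correlation_batch(np.swapaxes(P_spike[:, :, sel], 1, 2)))
        null_field = np.abs(_weighted_correlation_batch(np.swapaxes(P_field[:, :, sel], 1, 2)))
        # posterior column circular shift within this track's bins:
        # (S, Xt, T) where shuffle s rolls time bin j by shift_c[s, j]
        nb = int(sel.sum())
        shift_c = rng.integers(1, nb, size=(S, T)) if nb > 1 else np.zeros((S, T), int)
        rows = (np.arange(nb)[None, :, None] - shift_c[:, None, :]) % nb
        null_col_mat = np.take_along_axis(np.broadcast_to(sub[None], (S, nb, T)), rows, axis=1)
        null_col = np.abs(_weighted_correlation_batch(null_col_mat))
        nulls = (null_spike, null_field, null_col)
        p_vals = tuple(_shuffle_p(n, obs) for n in nulls)
        sig = all(obs > np.nanquantile(n, 1 - alpha) for n in nulls)
        per_track[m.track_id] = TrackScore(float(r_signed), p_vals, sig, bias)
    return per_track


def assign_track(score: ReplayScore, config: AnalysisConfig | None = None) -> ReplayScore:
    """Resolve the event's track from per-track significance and bias.

    Single-track significant events take that track; multi-track events
    take the higher-bias track. Any assignment requires the Bayesian bias
    for that track to exceed the 60% threshold, otherwise the event is
    discarded.
    """
    config = config or AnalysisConfig()
    sig = score.significant_tracks
    if not sig:
        score.assigned_track = None
        score.discarded = False
        return score
    best = max(sig, key=lambda t: score.per_track[t].bias)
    if score.per_track[best].bias > config.bias_threshold:
        score.assigned_track = best
        score.discarded = False
    else:
        score.assigned_track = None
        score.discarded = True
    return score


def split_event(
    session: Session,
    event: CandidateEvent,
    config: AnalysisConfig | None = None,
    units: list[Unit] | None = None,
) -> list[CandidateEvent]:
    """Split a failed candidate at the MUA minimum of its middle third.

    Returns the halves that still satisfy the candidate criteria
    (duration and unit count); each should then be scored independently
    at the stricter alpha. A flat middle third splits at the center.
    """
    config = config or AnalysisConfig()
    units = units if units is not None else session.units
    t, z = mua_trace(units, event.start_s, event.end_s,
                     config.mua_bin_s, config.mua_smooth_sd_s)
    dur = event.duration_s
    lo, hi = event.start_s + dur / 3, event.start_s + 2 * dur / 3
    sel = (t >= lo) & (t < hi)
    if sel.any() and np.ptp(z[sel]) > 1e-12:
        zw, tw = z[sel], t[sel]
        # ties (a plateau at the minimum) break to the plateau's middle, so
        # an exactly flat middle third splits at the event center
        at_min = np.flatnonzero(zw <= zw.min() + 1e-12)
        mid = float(tw[at_min[len(at_min) // 2]])
    else:
        mid = event.start_s + dur / 2
    halves = []
    for s, e in ((event.start_s, mid), (mid, event.end_s)):
        if e - s < config.event_min_duration_s:
            continue
        active = {u.unit_id for u in units if session.spikes_in(u, s, e).size > 0}
        if len(active) < config.event_min_units:
            continue
        halves.append(CandidateEvent(s, e, event.peak_mua_z, event.peak_ripple_z,
                                     active, event.epoch))
    return halves


def label_state(
    score: ReplayScore,
    epoch_label: str,
    epoch_track: int | None,
    sleep_mask: SleepMask | None,
) -> str:
    """Behavioral-state label for an assigned event.

    Rest-epoch events are sleep replay when the 1-min bin containing the
    event is putative sleep, otherwise rest replay; run-epoch events are
    awake-local when the decoded track matches the current track, else
    awake-remote.
    """
    if score.assigned_track is None:
        raise ValueError("event has no assigned track")
    mid = (score.event.start_s + score.event.end_s) / 2
    if epoch_track is not None:
        return "awake-local" if score.assigned_track == epoch_track else "awake-remote"
    if sleep_mask is not None and sleep_mask.is_sleep_at(mid):
        return "sleep"
    return "rest"


# --------------------------------------------------------------------------
# decoding-free SWR classification by track-selective cells


def classify_swr_by_selective_cells(
    events: list[CandidateEvent],
    selective: dict[str, list[int]],
    margin: float = 0.2,
) -> list[int | None]:
    """Label candidate SWR events by selective-cell participation.

    For each event, the fraction of each track's selective place cells
    that are active; the event takes a track when one fraction exceeds
    the other by more than ``margin``. Returns one label (1, 2, or None)
    per event.
    """
    t1, t2 = selective.get("t1_only", []), selective.get("t2_only", [])
    labels: list[int | None] = []
    for ev in events:
        if not t1 or not t2:
            labels.append(None)
            continue
        p1 = len(ev.participating_units & set(t1)) / len(t1)
        p2 = len(ev.participating_units & set(t2)) / len(t2)
        if p1 - p2 > margin:
            labels.append(1)
        elif p2 - p1 > margin:
            labels.append(2)
        else:
            labels.append(None)
    return labels


def dual_cell_event_stats(
    session: Session,
    events: list[CandidateEvent],
    labels: list[int | None],
    dual_ids: list[int],
) -> pd.DataFrame:
    """Per dual-track-cell firing-rate and participation differences.

    Within the labeled track-1 and track-2 event sets, each dual-track
    cell's in-event firing rate and participation fraction; the returned
    table holds the track-1 minus track-2 differences.
    """
    units = {u.unit_id: u for u in session.units}
    by_track = {1: [], 2: []}
    for ev, lab in zip(events, labels):
        if lab in (1, 2):
            by_track[lab].append(ev)
    rows = []
    for uid in dual_ids:
        u = units[uid]
        stats = {}
        for tid in (1, 2):
            evs = by_track[tid]
            if not evs:
                stats[tid] = (np.nan, np.nan)
                continue
            total_t = sum(e.duration_s for e in evs)
            n_spk = sum(session.spikes_in(u, e.start_s, e.end_s).size for e in evs)
            part = np.mean([session.spikes_in(u, e.start_s, e.end_s).size > 0 for e in evs])
            stats[tid] = (n_spk / total_t if total_t > 0 else np.nan, float(part))
        rows.append({
            "unit_id": uid,
            "rate_diff_hz": stats[1][0] - stats[2][0],
            "participation_diff": stats[1][1] - stats[2][1],
        })
    return pd.DataFrame(rows)
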