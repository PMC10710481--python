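"""Theta-cycle detection and theta-sequence analysis.

Theta cycles are found on the theta-band filtered LFP by a peak-trough
alternation scan with an amplitude threshold of 25% of the signal's
median amplitude (consecutive same-type extrema collapse to the larger
one). Cycles are kept when the animal is running (speed >= 5 cm/s)
outside the reward zones and the cycle lasts 80-200 ms.

Each cycle (one 2-pi phase window, trough to trough) is decoded in 10-ms
windows with the smoothed directional ratemaps of the lap it occurred in;
cycles with fewer than 2 active units are skipped. Per-cycle posteriors
are re-registered on the animal's current position (+/- 40 cm), mirrored
for one running direction, and averaged; sequences are scored by weighted
correlation against three shuffle nulls (spike-train circular shift,
posterior-position circular shift, and circular shift of the decoded
phase axis per position bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LinearizedPosition
from .config import AnalysisConfig
from .decoder import count_spikes
from .lfp import BandSignal
from .placefields import RateMapSet, _direction_sign, compute_ratemaps
from .replay import _weighted_correlation_batch, weighted_correlation
from .session import Session


@dataclass
class ThetaCycle:
    start_s: float            # trough
    end_s: float              # next trough
    position_cm: float
    direction: int            # +1 outbound, -1 inbound
    speed_cms: float
    lap: int = -1
    n_active_units: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _alternating_extrema(x: np.ndarray, threshold: float):
    """Indices and kinds (+1 peak / -1 trough) of alternating extrema.

    Local extrema below the amplitude threshold are dropped; consecutive
    extrema of the same kind collapse to the most extreme one, matching a
    brute-force alternation scan.
    """
    d = np.diff(x)
    sign = np.sign(d)
    # indices where slope sign changes
    turn = np.where(np.diff(sign) != 0)[0] + 1
    ext = []
    for i in turn:
        kind = 1 if x[i] >= x[i - 1] and x[i] >= x[i + 1] else -1
        if abs(x[i]) >= threshold:
            ext.append((i, kind))
    out: list[tuple[int, int]] = []
    for i, kind in ext:
        if out and out[-1][1] == kind:
            prev_i, _ = out[-1]
            if (kind == 1 and x[i] > x[prev_i]) or (kind == -1 and x[i] < x[prev_i]):
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    return out


def detect_theta_cycles(
    theta: BandSignal,
    lin: LinearizedPosition,
    epoch: tuple[float, float],
    config: AnalysisConfig | None = None,
) -> list[ThetaCycle]:
    """Detect theta cycles (trough to trough) within one run epoch."""
    config = config or AnalysisConfig()
    t = theta.times()
    sel = (t >= epoch[0]) & (t < epoch[1])
    x = theta.filtered[sel]
    tt = t[sel]
    if x.size < 3 or np.ptp(x) == 0:
        return []
    threshold = config.theta_amp_fraction * float(np.median(theta.amplitude[sel]))
    ext = _alternating_extrema(x, threshold)
    troughs = [i for i, kind in ext if kind == -1]
    dirs = _direction_sign(lin)
    cycles = []
    for i0, i1 in zip(troughs[:-1], troughs[1:]):
        start, end = float(tt[i0]), float(tt[i1])
        dur = end - start
        if not (config.theta_cycle_min_s <= dur <= config.theta_cycle_max_s):
            continue
        mid = (start + end) / 2
        speed = float(lin.interp_speed(np.array([mid]))[0])
        if speed < config.theta_speed_min_cms:
            continue
        pos = float(lin.interp_position(np.array([mid]))[0])
        if pos <= config.end_zone_cm or pos >= lin.track_length_cm - config.end_zone_cm:
            continue
        j = int(np.searchsorted(lin.time_s, mid))
        j = min(max(j, 0), dirs.size - 1)
        direction = int(dirs[j]) or 1
        cycles.append(ThetaCycle(start, end, pos, direction, speed))
    return cycles


def lap_directional_maps(
    session: Session,
    lin: LinearizedPosition,
    lap_table: pd.DataFrame,
    unit_ids: list[int],
    config: AnalysisConfig | None = None,
) -> dict[tuple[int, int], RateMapSet]:
    """Smoothed directional ratemaps per lap (2-cm bins, Gaussian sd 1 bin)."""
    config = config or AnalysisConfig()
    maps: dict[tuple[int, int], RateMapSet] = {}
    for _, row in lap_table.iterrows():
        for d in (1, -1):
            try:
                maps[(int(row["lap"]), d)] = compute_ratemaps(
                    session, lin, unit_ids, [(row["start_s"], row["end_s"])],
                    bin_size_cm=config.theta_bin_cm,
                    speed_window_cms=(config.ratemap_speed_min_cms, config.ratemap_speed_max_cms),
                    smooth_sd_bins=config.ratemap_smooth_sd_bins,
                    direction=d,
                )
            except ValueError:
                continue
    return maps


@dataclass
class DecodedCycle:
    cycle: ThetaCycle
    posterior: np.ndarray     # (n_bins, n_windows), this track only
    bin_centers: np.ndarray
    counts: np.ndarray
    unit_ids: list[int]
    lap_map: RateMapSet


def decode_theta_windows(
    session: Session,
    cycles: list[ThetaCycle],
    lap_table: pd.DataFrame,
    lap_maps: dict[tuple[int, int], RateMapSet],
    unit_ids: list[int],
    config: AnalysisConfig | None = None,
) -> list[DecodedCycle]:
    """Decode each theta cycle in 10-ms windows with its lap's directional map.

    The cycle spans one 2-pi window of theta phase (trough to trough);
    because unwrapped phase is monotone in time, assigning spikes by
    interpolated phase within the window is the same as taking spikes in
    the cycle's time span, which is what is binned here. Cycles with
    fewer than 2 active units are excluded.
    """
    config = config or AnalysisConfig()
    from .decoder import decode

    out: list[DecodedCycle] = []
    for cyc in cycles:
        mid = (cyc.start_s + cyc.end_s) / 2
        hit = lap_table[(lap_table["start_s"] <= mid) & (mid < lap_table["end_s"])]
        if hit.empty:
            continue
        lap = int(hit["lap"].iloc[0])
        m = lap_maps.get((lap, cyc.direction))
        if m is None:
            continue
        tau = config.decode_window_theta_s
        counts, starts = count_spikes(session, unit_ids, cyc.start_s, cyc.end_s, tau)
        if counts.shape[1] < 2:
            continue
        n_active = int((counts.sum(axis=1) > 0).sum())
        if n_active < config.theta_min_active_units:
            continue
        cyc.lap = lap
        cyc.n_active_units = n_active
        post = decode(counts, [m], unit_ids, tau, starts,
                      rate_floor_hz=config.rate_floor_hz)
        out.append(DecodedCycle(cyc, post.probs, m.bin_centers, counts, unit_ids, m))
    return out


def center_posterior(dc: DecodedCycle, config: AnalysisConfig | None = None) -> np.ndarray:
    """Re-register a cycle posterior on the animal's position (+/- 40 cm).

    The row holding the animal's true position moves to the center; the
    inbound direction is mirrored so "ahead of the animal" is always the
    positive half. Rows sliding off the track pad with zeros.
    """
    config = config or AnalysisConfig()
    bin_cm = float(dc.bin_centers[1] - dc.bin_centers[0])
    k = int(round(config.theta_center_cm / bin_cm))
    n_bins, n_t = dc.posterior.shape
    p0 = int(np.clip(np.round((dc.cycle.position_cm - dc.bin_centers[0]) / bin_cm), 0, n_bins - 1))
    out = np.zeros((2 * k + 1, n_t))
    for offset in range(-k, k + 1):
        src = p0 + offset
        if 0 <= src < n_bins:
            out[offset + k] = dc.posterior[src]
    if dc.cycle.direction == -1:
        out = out[::-1]
    return out


@dataclass
class ThetaSequenceResult:
    cycles: pd.DataFrame           # per decoded cycle: r, p-values, significant
    average_posterior: np.ndarray  # centered (+/-40 cm) x time, mean over cycles
    centered_axis_cm: np.ndarray
    n_cycles: int
    n_significant: int


def score_theta_significance(
    session: Session,
    dc: DecodedCycle,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    n_shuffles: int | None = None,
) -> tuple[float, tuple[float, float, float], bool]:
    """Score one decoded cycle against the three theta shuffle nulls.

    The score is the signed weighted correlation of the direction-
    rectified posterior (forward sweeps score positive); significance
    requires beating the 95th percentile of all three shuffle
    distributions.
    """
    config = config or AnalysisConfig()
    S = config.n_shuffles if n_shuffles is None else n_shuffles
    rng = rng or np.random.default_rng(config.seed)
    tau = config.decode_window_theta_s
    flip = dc.cycle.direction == -1

    def rectify(p):
        return p[..., ::-1, :] if flip else p

    obs = weighted_correlation(rectify(dc.posterior))
    if not np.isfinite(obs):
        return np.nan, (1.0, 1.0, 1.0), False
    F = dc.lap_map.matrix(dc.unit_ids)
    logF = np.log(np.maximum(F, config.rate_floor_hz))
    fsum = F.sum(axis=0)
    U, X = F.shape
    T = dc.counts.shape[1]
    from .replay import _decode_joint, _shuffle_p

    # 1. spike-train circular shift (re-decode)
    shift_t = rng.integers(1, T, size=(S, U)) if T > 1 else np.zeros((S, U), int)
    col = (np.arange(T)[None, None, :] + shift_t[:, :, None]) % T
    counts_s = np.take_along_axis(np.broadcast_to(dc.counts, (S, U, T)), col, axis=2)
    P1 = _decode_joint(counts_s, logF[None], np.broadcast_to(fsum, (S, X)), tau)
    null1 = _weighted_correlation_batch(rectify(np.swapaxes(P1, 1, 2)))
    # 2. circular shift of position (per time bin)
    shift_c = rng.integers(1, X, size=(S, T)) if X > 1 else np.zeros((S, T), int)
    rows = (np.arange(X)[None, :, None] - shift_c[:, None, :]) % X
    P2 = np.take_along_axis(np.broadcast_to(dc.posterior[None], (S, X, T)), rows, axis=1)
    null2 = _weighted_correlation_batch(rectify(P2))
    # 3. circular shift of decoded phase per position bin
    shift_r = rng.integers(1, T, size=(S, X)) if T > 1 else np.zeros((S, X), int)
    cols = (np.arange(T)[None, None, :] - shift_r[:, :, None]) % T
    P3 = np.take_along_axis(np.broadcast_to(dc.posterior[None], (S, X, T)), cols, axis=2)
    null3 = _weighted_correlation_batch(rectify(P3))
    nulls = (null1, null2, null3)
    p_vals = tuple(_shuffle_p(n, obs) for n in nulls)
    sig = all(obs > np.nanquantile(n[np.isfinite(n)], 1 - config.alpha)
              for n in nulls if np.isfinite(n).any())
    return float(obs), p_vals, sig


def average_theta_sequences(
    decoded: list[DecodedCycle],
    config: AnalysisConfig | None = None,
    score: bool = True,
    rng: np.random.Generator | None = None,
    n_shuffles: int | None = None,
    session: Session | None = None,
) -> ThetaSequenceResult:
    """Average centered cycle posteriors and tally significant sequences.

    Posteriors may differ in window count across cycles; each is
    column-normalized and time axes are aligned on the cycle start before
    averaging on the shortest common length.
    """
    config = config or AnalysisConfig()
    if not decoded:
        raise ValueError("no decoded cycles")
    bin_cm = float(decoded[0].bin_centers[1] - decoded[0].bin_centers[0])
    k = int(round(config.theta_center_cm / bin_cm))
    min_t = min(dc.posterior.shape[1] for dc in decoded)
    acc = np.zeros((2 * k + 1, min_t))
    rows = []
    n_sig = 0
    rng = rng or np.random.default_rng(config.seed)
    for dc in decoded:
        acc += center_posterior(dc, config)[:, :min_t]
        r, p_vals, sig = (np.nan, (np.nan,) * 3, False)
        if score:
            r, p_vals, sig = score_theta_significance(session, dc, config, rng, n_shuffles)
        n_sig += int(sig)
        rows.append({
            "start_s": dc.cycle.start_s, "end_s": dc.cycle.end_s,
            "position_cm": dc.cycle.position_cm, "direction": dc.cycle.direction,
            "lap": dc.cycle.lap, "n_active_units": dc.cycle.n_active_units,
            "r": r, "p_spike": p_vals[0], "p_position": p_vals[1], "p_phase": p_vals[2],
            "significant": sig,
        })
    axis = (np.arange(2 * k + 1) - k) * bin_cm
    return ThetaSequenceResult(pd.DataFrame(rows), acc / len(decoded), axis,
                               len(decoded), n_sig)
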