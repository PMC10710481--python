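"""Synthetic two-track session generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes: two
linear tracks with globally remapped place fields between tracks (and
stable fields across exposures), lap-structured running with
theta-modulated, phase-precessing place-cell spiking, rest epochs with
sleep/wake sub-structure, ripple-band LFP bursts carrying time-compressed
replay sequences, and multi-unit activity with burst structure.

The seven-epoch protocol is PRE, RUN1_T1, RUN1_T2, POST1, RUN2_T1,
RUN2_T2, POST2. During the first exposure the animal runs a fixed number
of laps per track (many on track 1, few on track 2); re-exposures run for
a fixed duration. Every embedded replay event, lap and sleep interval is
recorded in a :class:`GroundTruth` object so downstream detection,
decoding and quantification stages can be validated without animal data.

All randomness flows through one seeded generator family; sub-streams are
derived from ``(seed, fixed offset)`` so a fixed config yields
byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .session import EPOCH_ORDER, LfpTrace, Session, Track, Unit

# fixed sub-stream offsets (second entry of the rng seed sequence)
_STREAM_FIELDS = 101
_STREAM_RUN = 200       # + epoch index
_STREAM_SLEEP = 300     # + epoch index
_STREAM_UNITS = 400

# per-channel gain for the (theta, ripple, delta) synthetic LFP components
_CHANNEL_GAINS = [(50.0, 8.0, 10.0), (8.0, 50.0, 8.0), (30.0, 3.0, 30.0)]
_LFP_NOISE_UV = 10.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic session.

    Defaults describe the study conditions the generator emulates: a
    200-cm track pair, 16 laps on track 1 vs few on track 2 during the
    first exposure, ~15-min re-exposures, 8-Hz theta, 25-Hz position
    tracking, and sleep replay rates of a few events per hundred seconds.
    """

    seed: int = 0
    n_cells_per_track: int = 50
    track_length_cm: float = 200.0
    n_laps_t1: int = 16
    n_laps_t2: int = 4
    run_speed_mean_cms: float = 30.0
    theta_freq_hz: float = 8.0
    peak_rate_hz: float = 15.0
    field_width_cm: float = 15.0          # Gaussian sd of the spatial tuning
    sleep_duration_s: float = 1800.0      # PRE and POST2; POST1 is twice this
    run2_duration_s: float = 900.0        # per-track re-exposure duration
    replay_rate_t1: float = 0.03          # events / s of true sleep
    replay_rate_t2: float = 0.02
    rest_replay_factor: float = 0.5       # rest-replay rate relative to sleep rate
    awake_replay_rate: float = 0.1        # events / s of immobility on track
    remote_fraction: float = 0.15         # awake replay of the other track (RUN2 only)
    reverse_fraction: float = 0.5         # reverse-order replay trajectories
    replay_compression: float = 15.0      # virtual / real running speed
    noise_rate_hz: float = 0.5            # baseline Poisson rate per unit (rest)
    run_noise_rate_hz: float = 0.05       # out-of-field rate while locomoting
    lfp_sample_rate_hz: float = 1000.0
    position_sample_rate_hz: float = 25.0  # video tracking at 25 fps
    dual_field_fraction: float = 0.4      # cells with fields on both tracks
    pause_duration_s: float = 12.0        # reward pause at each track end
    position_noise_cm: float = 0.1
    theta_mod_depth: float = 0.8
    pre_burst_rate: float = 0.01          # structureless population bursts in PRE
    n_silent_units: int = 6               # principal cells with no field
    n_fast_units: int = 3                 # narrow-waveform high-rate units
    fast_unit_rate_hz: float = 20.0
    # unsorted-hash surge during population bursts: multi-unit activity
    # pooled across channels rises sharply inside every ripple event
    mua_hash_event_rate_hz: float = 80.0

    def validate(self) -> "SyntheticConfig":
        rates = [
            self.replay_rate_t1, self.replay_rate_t2, self.awake_replay_rate,
            self.noise_rate_hz, self.peak_rate_hz, self.pre_burst_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.n_laps_t1 < 1 or self.n_laps_t2 < 1:
            raise ValueError("n_laps must be >= 1")
        return self


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    field_centers: dict[int, dict[int, float]]   # unit -> track -> center (cm)
    replay_schedule: pd.DataFrame                # start_s, end_s, track, direction, ...
    true_sleep_intervals: list[tuple[float, float]]
    lap_table: pd.DataFrame                      # lap, start_s, end_s, track, epoch

    def schedule_in(self, start: float, end: float) -> pd.DataFrame:
        s = self.replay_schedule
        return s[(s["start_s"] >= start) & (s["end_s"] <= end)]


@dataclass
class UnitMeta:
    unit_id: int
    half_width_us: float
    kind: str                                     # "place", "silent", "fast"


@dataclass
class EpochSim:
    """One simulated epoch, on a clock starting at 0."""

    duration: float
    position: pd.DataFrame                       # time_s, x_cm, y_cm
    spikes: dict[int, np.ndarray]                # unit -> times
    lfp: list[np.ndarray]                        # per channel, float32
    schedule: pd.DataFrame
    sleep_intervals: list[tuple[float, float]] = field(default_factory=list)
    lap_table: pd.DataFrame | None = None


_SCHEDULE_COLS = ["start_s", "end_s", "track", "direction", "x_start_cm", "x_end_cm", "kind"]


def _empty_schedule() -> pd.DataFrame:
    return pd.DataFrame(columns=_SCHEDULE_COLS)


def default_tracks(cfg: SyntheticConfig) -> dict[int, Track]:
    length = cfg.track_length_cm
    return {
        1: Track(1, length, (0.0, 0.0), (length, 0.0)),
        2: Track(2, length, (0.0, 100.0), (length, 100.0)),
    }


_REST_XY = (-80.0, 50.0)


def make_population(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Draw the unit roster and independent field maps for each track.

    Global remapping between tracks is implemented as independent draws of
    field centers; a configurable fraction of cells carries a field on both
    tracks. A handful of silent principal cells and narrow-waveform
    fast-spiking units are included to exercise cell classification.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng([cfg.seed, _STREAM_FIELDS])
    n = cfg.n_cells_per_track
    if n <= 0:
        raise ValueError("empty population")
    n_dual = int(round(cfg.dual_field_fraction * n))
    n_only = n - n_dual
    ids_t1 = list(range(n_only))
    ids_t2 = list(range(n_only, 2 * n_only))
    ids_dual = list(range(2 * n_only, 2 * n_only + n_dual))
    n_place = 2 * n_only + n_dual
    field_centers: dict[int, dict[int, float]] = {}
    lo, hi = 10.0, cfg.track_length_cm - 10.0
    for uid in ids_t1:
        field_centers[uid] = {1: float(rng.uniform(lo, hi))}
    for uid in ids_t2:
        field_centers[uid] = {2: float(rng.uniform(lo, hi))}
    for uid in ids_dual:
        field_centers[uid] = {1: float(rng.uniform(lo, hi)), 2: float(rng.uniform(lo, hi))}
    meta_rng = np.random.default_rng([cfg.seed, _STREAM_UNITS])
    units: list[UnitMeta] = []
    for uid in range(n_place):
        units.append(UnitMeta(uid, float(meta_rng.uniform(550, 900)), "place"))
    uid = n_place
    for _ in range(cfg.n_silent_units):
        units.append(UnitMeta(uid, float(meta_rng.uniform(550, 900)), "silent"))
        uid += 1
    for _ in range(cfg.n_fast_units):
        units.append(UnitMeta(uid, float(meta_rng.uniform(250, 450)), "fast"))
        uid += 1
    return units, field_centers


# --------------------------------------------------------------------------
# run epochs


def _run_position_template(cfg: SyntheticConfig, n_laps: int, rng: np.random.Generator):
    """Piecewise-linear position knots for an out-and-back lap epoch."""
    length = cfg.track_length_cm
    t, x = 0.0, 0.0
    kt, kx = [0.0], [0.0]
    laps, pauses = [], []

    def add_pause(duration: float):
        nonlocal t
        pauses.append((t, t + duration))
        t += duration
        kt.append(t)
        kx.append(x)

    def add_run(target: float):
        nonlocal t, x
        speed = cfg.run_speed_mean_cms * rng.uniform(0.85, 1.15)
        t += abs(target - x) / speed
        x = target
        kt.append(t)
        kx.append(x)

    add_pause(cfg.pause_duration_s * rng.uniform(0.8, 1.2))
    for lap in range(n_laps):
        lap_start = t
        add_run(length)
        add_pause(cfg.pause_duration_s * rng.uniform(0.8, 1.2))
        add_run(0.0)
        laps.append((lap, lap_start, t))
        add_pause(cfg.pause_duration_s * rng.uniform(0.8, 1.2))
    return np.array(kt), np.array(kx), laps, pauses


def _draw_poisson_spikes(rate: np.ndarray, dt: float, t0: float, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(rate * dt)
    idx = np.nonzero(counts)[0]
    if idx.size == 0:
        return np.empty(0)
    reps = counts[idx]
    lefts = t0 + np.repeat(idx, reps) * dt
    return np.sort(lefts + rng.random(lefts.size) * dt)


def _uniform_spikes(rate: float, start: float, end: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * max(end - start, 0.0))
    return np.sort(start + rng.random(n) * (end - start))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """FFT-shaped 1/f noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / (out.std() + 1e-12)


def _sequence_spikes(
    cfg: SyntheticConfig,
    centers: dict[int, float],
    t0: float,
    duration: float,
    x0: float,
    x1: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Spikes of one time-compressed trajectory sweep from x0 to x1."""
    out: dict[int, list[float]] = {}
    span = x1 - x0
    for uid, c in centers.items():
        frac = (c - x0) / span if span != 0 else 0.5
        if not (-0.1 <= frac <= 1.1):
            continue
        tc = t0 + np.clip(frac, 0.0, 1.0) * duration
        n = rng.poisson(1.5)
        if n == 0:
            continue
        times = np.clip(tc + rng.normal(0.0, 0.006, n), t0, t0 + duration - 1e-4)
        out.setdefault(uid, []).extend(times.tolist())
    return {uid: np.sort(np.array(v)) for uid, v in out.items()}


def _schedule_events(
    intervals: list[tuple[float, float]],
    rate: float,
    rng: np.random.Generator,
    min_gap: float = 1.0,
) -> list[float]:
    """Poisson event start times inside the given intervals, with a minimum gap."""
    starts: list[float] = []
    for a, b in intervals:
        n = rng.poisson(rate * (b - a))
        starts.extend((a + rng.random(n) * (b - a)).tolist())
    starts.sort()
    kept: list[float] = []
    for s in starts:
        if not kept or s - kept[-1] >= min_gap:
            kept.append(s)
    return kept


def _hash_surge_spikes(cfg: SyntheticConfig, start: float, duration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Ripple-envelope multi-unit hash spikes for one fast unit, one event."""
    n = rng.poisson(cfg.mua_hash_event_rate_hz * duration)
    tt = rng.random(n)
    keep = rng.random(n) < np.sin(np.pi * tt) ** 2
    return np.sort(start + tt[keep] * duration)


def _ripple_burst(lfp: list[np.ndarray], fs: float, start: float, duration: float,
                  rng: np.random.Generator, amp: float = 40.0) -> None:
    i0 = int(start * fs)
    n = int(duration * fs)
    if n <= 0:
        return
    tt = np.arange(n) / fs
    env = np.sin(np.pi * np.arange(n) / n) ** 2
    carrier = np.sin(2 * np.pi * rng.uniform(160, 220) * tt + rng.uniform(0, 2 * np.pi))
    burst = (amp * env * carrier).astype(np.float32)
    for ch, (_, g_rip, _) in zip(lfp, _CHANNEL_GAINS):
        seg = ch[i0:i0 + n]
        seg += (g_rip / 50.0) * burst[: seg.size]


def _position_samples(cfg, duration, x_of_t, track: Track, rng) -> pd.DataFrame:
    ts = np.arange(0.0, duration, 1.0 / cfg.position_sample_rate_hz)
    xl = x_of_t(ts)
    origin = np.asarray(track.start_xy)
    pts = origin[None, :] + xl[:, None] * track.axis[None, :]
    pts += rng.normal(0.0, cfg.position_noise_cm, pts.shape)
    return pd.DataFrame({"time_s": ts, "x_cm": pts[:, 0], "y_cm": pts[:, 1]})


def simulate_run_epoch(
    cfg: SyntheticConfig,
    track_id: int,
    n_laps: int,
    field_centers: dict[int, dict[int, float]] | None = None,
    units: list[UnitMeta] | None = None,
    stream: int = 0,
    allow_remote: bool = False,
) -> EpochSim:
    """Simulate one lap-running exposure on a single track.

    Position sweeps end-to-end ``n_laps`` times with reward pauses at the
    ends; place-cell spikes are an inhomogeneous Poisson process with
    Gaussian spatial tuning multiplied by theta modulation with linear
    phase precession through the field; awake replay sequences are
    injected during the end pauses; the LFP carries a theta oscillation
    while the animal moves.
    """
    cfg.validate()
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    if units is None or field_centers is None:
        units, field_centers = make_population(cfg)
    if not units:
        raise ValueError("empty population")
    rng = np.random.default_rng([cfg.seed, _STREAM_RUN + stream])
    track = default_tracks(cfg)[track_id]
    kt, kx, laps, pauses = _run_position_template(cfg, n_laps, rng)
    duration = float(kt[-1])
    fs = cfg.lfp_sample_rate_hz
    dt = 1.0 / fs
    n_grid = int(round(duration * fs))
    tg = np.arange(n_grid) * dt
    xg = np.interp(tg, kt, kx)
    vg = np.gradient(xg, dt)
    moving = np.abs(vg) > 5.0
    direction = np.sign(vg)
    theta_phase = 2 * np.pi * cfg.theta_freq_hz * tg

    sd = cfg.field_width_cm
    spikes: dict[int, np.ndarray] = {}
    for um in units:
        if um.kind == "fast":
            rate = np.full(n_grid, cfg.fast_unit_rate_hz)
        else:
            # pyramidal cells are near-silent out-of-field while locomoting
            # (including cells whose fields live on the other track); the
            # baseline rises to the rest level during immobility
            rate = np.where(moving, cfg.run_noise_rate_hz, cfg.noise_rate_hz)
            c = field_centers.get(um.unit_id, {}).get(track_id)
            if c is not None:
                g = cfg.peak_rate_hz * np.exp(-((xg - c) ** 2) / (2 * sd * sd))
                s = np.clip(direction * (xg - c), -2 * sd, 2 * sd)
                # linear phase precession referenced to the LFP trough
                # (trough of sin at 3*pi/2): a cell fires mid-cycle when the
                # animal crosses its field center, early when the field is
                # behind (s > 0), late when ahead; 0.8 * 2*pi total range so
                # the order never wraps within one trough-to-trough cycle
                phi_pref = np.pi / 2 - 0.8 * np.pi * s / (2 * sd)
                # squared raised cosine, normalized by its phase-average
                # (1 + m^2/2) so the field's mean rate stays at G while
                # spikes concentrate tightly near the preferred phase
                m = cfg.theta_mod_depth
                base = 1.0 + m * np.cos(theta_phase - phi_pref)
                mod = np.maximum(0.0, base) ** 2 / (1.0 + m * m / 2.0)
                rate = rate + np.where(moving, g * mod, 0.0)
        spikes[um.unit_id] = _draw_poisson_spikes(rate, dt, 0.0, rng)

    # LFP: movement-gated theta + pink noise; ripple bursts added per event
    lfp = []
    for g_theta, _, _ in _CHANNEL_GAINS:
        trace = _LFP_NOISE_UV * _pink_noise(n_grid, rng)
        trace += g_theta * np.sin(theta_phase) * moving
        lfp.append(trace.astype(np.float32))

    # awake replay during end pauses (immobility)
    sched_rows = []
    starts = _schedule_events(pauses, cfg.awake_replay_rate, rng)
    other = 2 if track_id == 1 else 1
    for s in starts:
        dur = float(rng.uniform(0.15, 0.35))
        if any(s >= b - dur for (a, b) in pauses if a <= s < b):
            continue
        remote = allow_remote and rng.random() < cfg.remote_fraction
        ev_track = other if remote else track_id
        centers = {u: c[ev_track] for u, c in field_centers.items() if ev_track in c}
        if len(centers) < 5:
            continue
        vspeed = cfg.replay_compression * cfg.run_speed_mean_cms
        span = min(vspeed * dur, cfg.track_length_cm - 10.0)
        rev = rng.random() < cfg.reverse_fraction
        x0 = float(rng.uniform(0.0, cfg.track_length_cm - span))
        x1 = x0 + span
        if rev:
            x0, x1 = x1, x0
        for uid, st in _sequence_spikes(cfg, centers, s, dur, x0, x1, rng).items():
            spikes[uid] = np.sort(np.concatenate([spikes[uid], st]))
        for um in units:
            if um.kind == "fast":
                surge = _hash_surge_spikes(cfg, s, dur, rng)
                spikes[um.unit_id] = np.sort(np.concatenate([spikes[um.unit_id], surge]))
        _ripple_burst(lfp, fs, s, dur, rng)
        sched_rows.append((s, s + dur, ev_track, -1 if rev else 1, x0, x1,
                           "awake_remote" if remote else "awake_local"))

    position = _position_samples(cfg, duration, lambda ts: np.interp(ts, kt, kx), track, rng)
    lap_table = pd.DataFrame(laps, columns=["lap", "start_s", "end_s"])
    lap_table["track"] = track_id
    schedule = pd.DataFrame(sched_rows, columns=_SCHEDULE_COLS) if sched_rows else _empty_schedule()
    return EpochSim(duration, position, spikes, lfp, schedule, [], lap_table)


# --------------------------------------------------------------------------
# rest / sleep epochs


def _sleep_segments(duration: float) -> list[tuple[float, float, str]]:
    """Alternating wake/sleep blocks aligned to 60-s boundaries."""
    segs: list[tuple[float, float, str]] = []
    t = 0.0
    first_awake = min(120.0, duration)
    segs.append((t, first_awake, "awake"))
    t = first_awake
    while t < duration:
        end = min(t + 600.0, duration)
        segs.append((t, end, "sleep"))
        t = end
        if t >= duration:
            break
        end = min(t + 60.0, duration)
        segs.append((t, end, "awake"))
        t = end
    return segs


def simulate_sleep_epoch(
    cfg: SyntheticConfig,
    field_centers: dict[int, dict[int, float]],
    duration: float,
    units: list[UnitMeta] | None = None,
    stream: int = 0,
    rate_t1: float | None = None,
    rate_t2: float | None = None,
    with_replay: bool = True,
) -> EpochSim:
    """Simulate a rest-box epoch with sleep sub-structure and replay bursts.

    Baseline low-rate spiking is punctuated by scheduled compressed
    trajectory sequences (each >= 5 units, 150-350 ms) whose content is
    drawn from the supplied field maps; ripple-band LFP power is elevated
    during each burst; putative-sleep structure comes from alternating
    wake/sleep blocks that modulate both movement and population rate.
    """
    cfg.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if with_replay and not field_centers:
        raise ValueError("field maps must be non-empty")
    if units is None:
        units, _ = make_population(cfg)
    rng = np.random.default_rng([cfg.seed, _STREAM_SLEEP + stream])
    segs = _sleep_segments(duration)
    sleep_iv = [(a, b) for a, b, k in segs if k == "sleep"]
    awake_iv = [(a, b) for a, b, k in segs if k == "awake"]

    # baseline spiking: slightly elevated population rate during sleep blocks
    spikes: dict[int, list[np.ndarray]] = {um.unit_id: [] for um in units}
    for um in units:
        base = cfg.fast_unit_rate_hz if um.kind == "fast" else cfg.noise_rate_hz
        for a, b, k in segs:
            r = base * (1.2 if k == "sleep" else 0.8)
            spikes[um.unit_id].append(_uniform_spikes(r, a, b, rng))

    fs = cfg.lfp_sample_rate_hz
    n_grid = int(round(duration * fs))
    tg = np.arange(n_grid) / fs
    state = np.zeros(n_grid, dtype=bool)
    for a, b in sleep_iv:
        state[int(a * fs):int(b * fs)] = True
    lfp = []
    for g_theta, _, g_delta in _CHANNEL_GAINS:
        trace = _LFP_NOISE_UV * _pink_noise(n_grid, rng)
        trace += g_delta * np.sin(2 * np.pi * 2.0 * tg) * state          # delta in sleep
        trace += 0.5 * g_theta * np.sin(2 * np.pi * cfg.theta_freq_hz * tg) * (~state)
        lfp.append(trace.astype(np.float32))

    sched_rows = []
    if with_replay:
        r1 = cfg.replay_rate_t1 if rate_t1 is None else rate_t1
        r2 = cfg.replay_rate_t2 if rate_t2 is None else rate_t2
        plans = [(1, r1, sleep_iv, "sleep"), (2, r2, sleep_iv, "sleep"),
                 (1, r1 * cfg.rest_replay_factor, awake_iv, "rest"),
                 (2, r2 * cfg.rest_replay_factor, awake_iv, "rest")]
        proposals = []
        for ev_track, rate, iv, kind in plans:
            for s in _schedule_events(iv, rate, rng):
                proposals.append((s, ev_track, kind))
        proposals.sort()
        last_end = -10.0
        for s, ev_track, kind in proposals:
            dur = float(rng.uniform(0.15, 0.35))
            if s - last_end < 0.5:
                continue
            if not any(a <= s and s + dur <= b for a, b in (sleep_iv if kind == "sleep" else awake_iv)):
                continue
            centers = {u: c[ev_track] for u, c in field_centers.items() if ev_track in c}
            if len(centers) < 5:
                continue
            vspeed = cfg.replay_compression * cfg.run_speed_mean_cms
            span = min(vspeed * dur, cfg.track_length_cm - 10.0)
            rev = rng.random() < cfg.reverse_fraction
            x0 = float(rng.uniform(0.0, cfg.track_length_cm - span))
            x1 = x0 + span
            if rev:
                x0, x1 = x1, x0
            seq = _sequence_spikes(cfg, centers, s, dur, x0, x1, rng)
            if len(seq) < 5:
                continue
            for uid, st in seq.items():
                spikes[uid].append(st)
            for um in units:
                if um.kind == "fast":
                    spikes[um.unit_id].append(_hash_surge_spikes(cfg, s, dur, rng))
            _ripple_burst(lfp, fs, s, dur, rng)
            sched_rows.append((s, s + dur, ev_track, -1 if rev else 1, x0, x1, kind))
            last_end = s + dur

    # structureless population bursts (random unit subset + ripple)
    if cfg.pre_burst_rate > 0:
        place_ids = [um.unit_id for um in units if um.kind == "place"]
        for s in _schedule_events([(0.0, duration)], cfg.pre_burst_rate, rng):
            if sched_rows and any(abs(s - r[0]) < 1.0 for r in sched_rows):
                continue
            dur = float(rng.uniform(0.12, 0.25))
            if s + dur > duration:
                continue
            chosen = rng.choice(place_ids, size=min(15, len(place_ids)), replace=False)
            for uid in chosen:
                spikes[uid].append(np.sort(s + rng.random(rng.poisson(2.0)) * dur))
            for um in units:
                if um.kind == "fast":
                    spikes[um.unit_id].append(_hash_surge_spikes(cfg, s, dur, rng))
            _ripple_burst(lfp, fs, s, dur, rng)

    merged = {uid: np.sort(np.concatenate(parts)) if parts else np.empty(0)
              for uid, parts in spikes.items()}

    # position: near-stationary during sleep blocks, slow wander while awake,
    # pausing around rest-replay events (awake replay occurs in stillness)
    ts = np.arange(0.0, duration, 1.0 / cfg.position_sample_rate_hz)
    awake_mask = np.zeros(ts.size, dtype=bool)
    for a, b in awake_iv:
        awake_mask |= (ts >= a) & (ts < b)
    for s, e, _, _, _, _, kind in sched_rows:
        if kind == "rest":
            awake_mask &= ~((ts >= s - 1.5) & (ts < e + 1.5))
    phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
    wx = 15.0 * np.sin(2 * np.pi * 0.06 * ts + phase1)
    wy = 15.0 * np.sin(2 * np.pi * 0.05 * ts + phase2)
    # ramp the wander gate over ~1 s so gating itself adds no position jumps
    n_ramp = max(1, int(cfg.position_sample_rate_hz))
    gate = np.convolve(awake_mask.astype(float), np.ones(n_ramp) / n_ramp, mode="same")
    x = _REST_XY[0] + gate * wx
    y = _REST_XY[1] + gate * wy
    # carry the wander offset into sleep so the position stays continuous
    x += rng.normal(0, cfg.position_noise_cm, ts.size)
    y += rng.normal(0, cfg.position_noise_cm, ts.size)
    position = pd.DataFrame({"time_s": ts, "x_cm": x, "y_cm": y})
    schedule = pd.DataFrame(sched_rows, columns=_SCHEDULE_COLS) if sched_rows else _empty_schedule()
    return EpochSim(duration, position, merged, lfp, schedule, sleep_iv, None)


# --------------------------------------------------------------------------
# full sessions


def simulate_session(cfg: SyntheticConfig) -> tuple[Session, GroundTruth]:
    """Assemble the full seven-epoch two-track protocol.

    Field maps are independent between tracks (global remapping) and
    identical across exposures of the same track (stable fields). Returns
    the session plus its ground truth on one continuous session clock.
    """
    cfg.validate()
    units, field_centers = make_population(cfg)
    lap_time = 2 * cfg.track_length_cm / cfg.run_speed_mean_cms + 2 * cfg.pause_duration_s
    n_laps_run2 = max(1, int(cfg.run2_duration_s // lap_time))

    epoch_sims: dict[str, EpochSim] = {}
    epoch_sims["PRE"] = simulate_sleep_epoch(
        cfg, field_centers, cfg.sleep_duration_s, units, stream=0, with_replay=False
    )
    epoch_sims["RUN1_T1"] = simulate_run_epoch(
        cfg, 1, cfg.n_laps_t1, field_centers, units, stream=1, allow_remote=False
    )
    epoch_sims["RUN1_T2"] = simulate_run_epoch(
        cfg, 2, cfg.n_laps_t2, field_centers, units, stream=2, allow_remote=False
    )
    epoch_sims["POST1"] = simulate_sleep_epoch(
        cfg, field_centers, 2 * cfg.sleep_duration_s, units, stream=3
    )
    epoch_sims["RUN2_T1"] = simulate_run_epoch(
        cfg, 1, n_laps_run2, field_centers, units, stream=4, allow_remote=True
    )
    epoch_sims["RUN2_T2"] = simulate_run_epoch(
        cfg, 2, n_laps_run2, field_centers, units, stream=5, allow_remote=True
    )
    epoch_sims["POST2"] = simulate_sleep_epoch(
        cfg, field_centers, cfg.sleep_duration_s, units, stream=6
    )

    # stitch epochs onto one session clock
    t0 = 0.0
    offsets: dict[str, float] = {}
    epoch_rows = []
    for label in EPOCH_ORDER:
        offsets[label] = t0
        epoch_rows.append({"label": label, "start_s": t0, "end_s": t0 + epoch_sims[label].duration})
        t0 += epoch_sims[label].duration
    epochs = pd.DataFrame(epoch_rows)
    total = t0

    spike_parts: dict[int, list[np.ndarray]] = {um.unit_id: [] for um in units}
    pos_parts, lfp_parts = [], [[] for _ in _CHANNEL_GAINS]
    sched_parts, lap_parts, sleep_iv = [], [], []
    for label in EPOCH_ORDER:
        sim, off = epoch_sims[label], offsets[label]
        for uid, st in sim.spikes.items():
            spike_parts[uid].append(st + off)
        pos = sim.position.copy()
        pos["time_s"] += off
        pos_parts.append(pos)
        for ci in range(len(_CHANNEL_GAINS)):
            lfp_parts[ci].append(sim.lfp[ci])
        if not sim.schedule.empty:
            sched = sim.schedule.copy()
            sched[["start_s", "end_s"]] += off
            sched["epoch"] = label
            sched_parts.append(sched)
        if sim.lap_table is not None:
            laps = sim.lap_table.copy()
            laps[["start_s", "end_s"]] += off
            laps["epoch"] = label
            lap_parts.append(laps)
        sleep_iv.extend((a + off, b + off) for a, b in sim.sleep_intervals)

    session_units = []
    for um in units:
        st = np.sort(np.concatenate(spike_parts[um.unit_id]))
        session_units.append(
            Unit(um.unit_id, st, um.half_width_us, mean_rate_hz=st.size / total)
        )
    lfp = [
        LfpTrace(ci, cfg.lfp_sample_rate_hz, np.concatenate(parts))
        for ci, parts in enumerate(lfp_parts)
    ]
    session = Session(
        units=session_units,
        position=pd.concat(pos_parts, ignore_index=True),
        lfp=lfp,
        epochs=epochs,
        tracks=default_tracks(cfg),
    ).validate()
    schedule = (
        pd.concat(sched_parts, ignore_index=True) if sched_parts
        else _empty_schedule().assign(epoch=pd.Series(dtype=object))
    )
    lap_table = pd.concat(lap_parts, ignore_index=True)
    truth = GroundTruth(field_centers, schedule, sleep_iv, lap_table)
    return session, truth
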