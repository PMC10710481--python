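"""Position cleaning, linearization, speed, and lap/immobility segmentation.

Tracking glitches (reflections, lost LEDs) are removed by a distance-jump
rule (default 40 cm between consecutive samples) and an implied-speed rule
(default 100 cm/s); discarded samples are linearly interpolated. Cleaned
2-D positions are projected onto each track's axis to give the distance
traveled along the track; speed is a centered-difference derivative,
smoothed with a short moving average before any thresholding. A lap is one
full out-and-back traversal between the two reward end zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .session import Session, Track


def clean_position(
    raw: pd.DataFrame,
    jump_limit_cm: float = 40.0,
    speed_limit_cms: float = 100.0,
) -> pd.DataFrame:
    """Remove jump/speed-violating samples and interpolate across them.

    A sample is discarded when its distance from the last accepted sample
    exceeds ``jump_limit_cm`` or implies a speed above ``speed_limit_cms``.
    The scan is anchored on the last accepted sample, so a run of
    off-track points after a single glitch is removed as a block.
    Idempotent: a clean trace passes through unchanged.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 position samples")
    t = raw["time_s"].to_numpy(float)
    xy = raw[["x_cm", "y_cm"]].to_numpy(float)
    good = np.ones(len(raw), dtype=bool)
    last = 0
    for i in range(1, len(raw)):
        d = float(np.hypot(*(xy[i] - xy[last])))
        dt = t[i] - t[last]
        if d > jump_limit_cm or (dt > 0 and d / dt > speed_limit_cms):
            good[i] = False
        else:
            last = i
    if good.sum() < 2:
        raise ValueError("tracking unusable: all samples removed")
    out = raw.copy()
    for col in ("x_cm", "y_cm"):
        out.loc[~good, col] = np.interp(t[~good], t[good], raw[col].to_numpy(float)[good])
    return out


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(np.pad(x, (n // 2, n - 1 - n // 2), mode="edge"), kernel, mode="valid")


@dataclass
class LinearizedPosition:
    """Per-sample linear coordinate on a track (NaN while off the track)."""

    time_s: np.ndarray
    position_cm: np.ndarray      # distance along the track axis; NaN off-track
    speed_cms: np.ndarray        # smoothed 2-D speed, >= 0
    on_track: np.ndarray         # bool
    track_id: int
    track_length_cm: float

    def interp_position(self, times: np.ndarray) -> np.ndarray:
        mask = self.on_track
        return np.interp(times, self.time_s[mask], self.position_cm[mask])

    def interp_speed(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.time_s, self.speed_cms)


def linearize_and_speed(
    cleaned: pd.DataFrame,
    track: Track,
    config: AnalysisConfig | None = None,
    off_track_tol_cm: float = 20.0,
) -> LinearizedPosition:
    """Project cleaned 2-D positions onto the track axis and compute speed."""
    config = config or AnalysisConfig()
    t = cleaned["time_s"].to_numpy(float)
    xy = cleaned[["x_cm", "y_cm"]].to_numpy(float)
    origin = np.asarray(track.start_xy, float)
    axis = track.axis  # raises on degenerate geometry
    rel = xy - origin[None, :]
    lin = rel @ axis
    perp = np.abs(rel @ np.array([-axis[1], axis[0]]))
    on = (perp <= off_track_tol_cm) & (lin >= -off_track_tol_cm) & (lin <= track.length_cm + off_track_tol_cm)
    lin_clipped = np.clip(lin, 0.0, track.length_cm)
    pos = np.where(on, lin_clipped, np.nan)
    vel = np.gradient(xy, t, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if t.size > 1:
        dt = float(np.median(np.diff(t)))
        n = max(1, int(round(config.speed_smooth_s / dt)))
        speed = _moving_average(speed, n)
    return LinearizedPosition(t, pos, speed, on, track.track_id, track.length_cm)


@dataclass
class BehaviorSummary:
    track_id: int
    epoch_label: str
    n_laps: int
    time_immobile_s: float
    time_mobile_s: float
    mean_moving_speed_cms: float
    epoch_duration_s: float


def segment_behavior(
    lin: LinearizedPosition,
    epoch: tuple[float, float],
    epoch_label: str = "",
    immobility_speed_cms: float = 4.0,
    end_zone_cm: float = 20.0,
) -> tuple[BehaviorSummary, pd.DataFrame]:
    """Count laps and split epoch time into mobile/immobile.

    A lap is a full out-and-back traversal: a visit sequence end A ->
    end B -> end A (either starting end). Immobile time is total time
    with smoothed speed below the threshold; mobile is the rest, so
    the two partition the epoch duration.
    """
    start, end = epoch
    sel = (lin.time_s >= start) & (lin.time_s < end)
    if sel.sum() < 2:
        raise ValueError("epoch shorter than one position sample")
    t = lin.time_s[sel]
    pos = lin.position_cm[sel]
    speed = lin.speed_cms[sel]
    dt = np.diff(t, append=t[-1] + np.median(np.diff(t)))
    immobile = float(dt[speed < immobility_speed_cms].sum())
    duration = float(end - start)
    mobile = duration - immobile
    moving = speed >= immobility_speed_cms
    mean_speed = float(speed[moving].mean()) if moving.any() else 0.0

    # end-zone visit sequence, consecutive repeats collapsed
    length = lin.track_length_cm
    zone = np.where(pos <= end_zone_cm, 0, np.where(pos >= length - end_zone_cm, 1, -1))
    zone[np.isnan(pos)] = -1
    visits: list[tuple[int, float]] = []
    for zi, ti in zip(zone, t):
        if zi >= 0 and (not visits or visits[-1][0] != zi):
            visits.append((int(zi), float(ti)))
    laps = []
    i = 0
    lap_idx = 0
    while i + 2 < len(visits):
        a, b, c = visits[i][0], visits[i + 1][0], visits[i + 2][0]
        if a == c and a != b:
            laps.append({"lap": lap_idx, "start_s": visits[i][1], "end_s": visits[i + 2][1],
                         "track": lin.track_id, "epoch": epoch_label})
            lap_idx += 1
            i += 2
        else:
            i += 1
    lap_table = pd.DataFrame(laps, columns=["lap", "start_s", "end_s", "track", "epoch"])
    summary = BehaviorSummary(
        track_id=lin.track_id,
        epoch_label=epoch_label,
        n_laps=len(laps),
        time_immobile_s=immobile,
        time_mobile_s=mobile,
        mean_moving_speed_cms=mean_speed,
        epoch_duration_s=duration,
    )
    return summary, lap_table


def linearize_session(session: Session, config: AnalysisConfig | None = None):
    """Clean the session's position and linearize it for each track.

    Cleaning runs within each behavioral epoch separately: the animal is
    carried between the rest box and the tracks, so the jump rule must
    not treat an epoch-boundary relocation as a tracking glitch. Returns
    ``(cleaned position, {track_id: LinearizedPosition})`` where each
    linearization covers the full session clock (NaN off that track).
    """
    config = config or AnalysisConfig()
    parts = []
    t = session.position["time_s"].to_numpy(float)
    for _, row in session.epochs.iterrows():
        seg = session.position[(t >= row["start_s"]) & (t < row["end_s"])]
        if len(seg) < 2:
            continue
        parts.append(clean_position(
            seg, config.position_jump_limit_cm, config.position_speed_limit_cms
        ))
    if not parts:
        raise ValueError("tracking unusable: no epoch has enough samples")
    cleaned = pd.concat(parts, ignore_index=True)
    lins = {
        tid: linearize_and_speed(cleaned, track, config)
        for tid, track in session.tracks.items()
    }
    return cleaned, lins


def session_behavior(session: Session, config: AnalysisConfig | None = None):
    """Behavior summaries and lap tables for every run epoch of a session."""
    config = config or AnalysisConfig()
    _, lins = linearize_session(session, config)
    summaries, lap_tables = [], []
    from .session import RUN_EPOCHS

    for label, tid in RUN_EPOCHS.items():
        try:
            bounds = session.epoch_bounds(label)
        except KeyError:
            continue
        summ, laps = segment_behavior(
            lins[tid], bounds, label, config.immobility_speed_cms, config.end_zone_cm
        )
        summaries.append(summ)
        lap_tables.append(laps)
    lap_table = (
        pd.concat(lap_tables, ignore_index=True)
        if lap_tables
        else pd.DataFrame(columns=["lap", "start_s", "end_s", "track", "epoch"])
    )
    return summaries, lap_table, lins
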