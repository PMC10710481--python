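"""Cell classification, occupancy-normalized ratemaps, and population-vector
remapping analysis.

Principal cells have broad waveforms (half-width half-max > 500 us) and a
session-wide mean rate below 5 Hz; a principal cell is a place cell on a
track when its unsmoothed ratemap there peaks above 1 Hz, with spikes
speed-filtered to 4-50 cm/s. Ratemaps are spike histograms divided by
dwell time per position bin (10-cm bins for decoding, 2-cm for display
and theta maps; only unsmoothed maps feed Bayesian decoding). Remapping
between map sets is quantified by per-bin Pearson correlation of the
population rate vectors against a unit-identity permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .behavior import LinearizedPosition
from .config import AnalysisConfig
from .session import Session


@dataclass
class RateMapSet:
    """Per-unit firing-rate vectors over position bins of one track."""

    track_id: int
    bin_edges: np.ndarray
    rates: dict[int, np.ndarray]    # Hz; zero-occupancy bins are NaN
    occupancy_s: np.ndarray
    smoothed: bool = False

    @property
    def bin_size_cm(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.rates)

    def matrix(self, unit_ids: list[int] | None = None, fill: float = 0.0) -> np.ndarray:
        ids = self.unit_ids if unit_ids is None else unit_ids
        m = np.stack([self.rates[u] for u in ids])
        return np.nan_to_num(m, nan=fill)

    def peak(self, unit_id: int) -> float:
        r = self.rates[unit_id]
        return float(np.nanmax(r)) if np.isfinite(r).any() else 0.0


def _direction_sign(lin: LinearizedPosition) -> np.ndarray:
    pos = np.nan_to_num(lin.position_cm, nan=0.0)
    d = np.gradient(pos, lin.time_s)
    # smooth so brief reversals at turn-around do not fragment passes
    d = gaussian_filter1d(d, sigma=3)
    return np.sign(d)


def compute_ratemaps(
    session: Session,
    lin: LinearizedPosition,
    unit_ids: list[int],
    intervals: list[tuple[float, float]],
    bin_size_cm: float = 10.0,
    speed_window_cms: tuple[float, float] = (4.0, 50.0),
    smooth_sd_bins: float | None = None,
    direction: int | None = None,
) -> RateMapSet:
    """Occupancy-normalized ratemaps over the given time intervals.

    ``direction`` of +1/-1 restricts both occupancy and spikes to
    outbound/inbound passes. Zero-occupancy bins are NaN in the rate
    vectors (the occupancy vector is returned so callers can mask).
    """
    edges = np.arange(0.0, lin.track_length_cm + bin_size_cm / 2, bin_size_cm)
    if edges[-1] < lin.track_length_cm - 1e-9:
        edges = np.append(edges, lin.track_length_cm)
    n_bins = edges.size - 1
    t = lin.time_s
    dt = float(np.median(np.diff(t)))
    in_iv = np.zeros(t.size, dtype=bool)
    for a, b in intervals:
        in_iv |= (t >= a) & (t < b)
    ok = (
        in_iv
        & lin.on_track
        & (lin.speed_cms >= speed_window_cms[0])
        & (lin.speed_cms <= speed_window_cms[1])
    )
    if direction is not None:
        ok &= _direction_sign(lin) == direction
    occ = np.histogram(lin.position_cm[ok], bins=edges)[0] * dt
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy in requested intervals")

    units = {u.unit_id: u for u in session.units}
    rates: dict[int, np.ndarray] = {}
    # spike-time masks reuse the same speed/interval/direction rules
    ok_t = t[ok]
    for uid in unit_ids:
        st = units[uid].spike_times
        if st.size == 0:
            counts = np.zeros(n_bins)
        else:
            sel = np.zeros(st.size, dtype=bool)
            for a, b in intervals:
                sel |= (st >= a) & (st < b)
            idx = np.searchsorted(t, st[sel])
            idx = np.clip(idx, 0, t.size - 1)
            keep = ok[idx]
            spos = lin.interp_position(st[sel][keep])
            counts = np.histogram(spos, bins=edges)[0].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ > 0, counts / np.where(occ > 0, occ, 1.0), np.nan)
        rates[uid] = rate
    rms = RateMapSet(lin.track_id, edges, rates, occ, smoothed=False)
    if smooth_sd_bins:
        sm = {
            uid: gaussian_filter1d(np.nan_to_num(r, nan=0.0), sigma=smooth_sd_bins)
            for uid, r in rates.items()
        }
        rms = RateMapSet(lin.track_id, edges, sm, occ, smoothed=True)
    return rms


def classify_units(
    session: Session,
    lins: dict[int, LinearizedPosition],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Classify units as principal cells and per-track place cells.

    Returns a roster with one row per unit: ``principal`` (half-width
    > 500 us and mean rate < 5 Hz), per-track place flags and unsmoothed
    peak rates. Units lacking a half-width are excluded.
    """
    config = config or AnalysisConfig()
    from .session import RUN_EPOCHS

    track_intervals: dict[int, list[tuple[float, float]]] = {1: [], 2: []}
    for label, tid in RUN_EPOCHS.items():
        try:
            track_intervals[tid].append(session.epoch_bounds(label))
        except KeyError:
            pass
    rows = []
    uids = [u.unit_id for u in session.units if np.isfinite(u.half_width_us)]
    maps = {}
    for tid, iv in track_intervals.items():
        if iv and tid in lins:
            maps[tid] = compute_ratemaps(
                session, lins[tid], uids, iv,
                bin_size_cm=config.classification_bin_cm,
                speed_window_cms=(config.ratemap_speed_min_cms, config.ratemap_speed_max_cms),
            )
    for u in session.units:
        if not np.isfinite(u.half_width_us):
            continue
        principal = (
            u.half_width_us > config.principal_min_hwhm_us
            and u.mean_rate_hz < config.principal_max_rate_hz
        )
        row = {"unit_id": u.unit_id, "principal": principal}
        for tid in (1, 2):
            peak = maps[tid].peak(u.unit_id) if tid in maps else 0.0
            row[f"peak_t{tid}"] = peak
            row[f"place_t{tid}"] = bool(principal and peak > config.place_min_peak_hz)
        rows.append(row)
    return pd.DataFrame(rows)


def place_cells(roster: pd.DataFrame, track_id: int) -> list[int]:
    return roster.loc[roster[f"place_t{track_id}"], "unit_id"].astype(int).tolist()


def track_selective_cells(roster: pd.DataFrame) -> dict[str, list[int]]:
    """Split place cells into track-1-only, track-2-only, and dual-track sets."""
    t1 = roster["place_t1"].to_numpy(bool)
    t2 = roster["place_t2"].to_numpy(bool)
    ids = roster["unit_id"].to_numpy(int)
    return {
        "t1_only": ids[t1 & ~t2].tolist(),
        "t2_only": ids[t2 & ~t1].tolist(),
        "dual": ids[t1 & t2].tolist(),
    }


def pv_correlation(
    maps_a: RateMapSet,
    maps_b: RateMapSet,
    n_shuffles: int = 0,
    rng: np.random.Generator | None = None,
):
    """Population-vector correlation between two map sets, bin by bin.

    For each position bin, the Pearson correlation across units between
    the two population rate vectors. The null distribution permutes unit
    identities in the second map set. Returns ``(per-bin r, mean r,
    shuffle means)``. Symmetric in its arguments and invariant to scaling
    either map set.
    """
    common = sorted(set(maps_a.rates) & set(maps_b.rates))
    if len(common) < 2:
        raise ValueError("need at least 2 common units")
    A = maps_a.matrix(common)
    B = maps_b.matrix(common)

    def _pv(Bm: np.ndarray) -> np.ndarray:
        out = np.full(A.shape[1], np.nan)
        for j in range(A.shape[1]):
            a, b = A[:, j], Bm[:, j]
            if a.std() > 0 and b.std() > 0:
                out[j] = np.corrcoef(a, b)[0, 1]
        return out

    per_bin = _pv(B)
    mean_r = float(np.nanmean(per_bin))
    shuffles = np.empty(n_shuffles)
    if n_shuffles:
        rng = rng or np.random.default_rng(0)
        for s in range(n_shuffles):
            perm = rng.permutation(len(common))
            shuffles[s] = np.nanmean(_pv(B[perm]))
    return per_bin, mean_r, shuffles
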