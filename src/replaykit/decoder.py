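"""Naive Bayes reconstruction of position from population spike counts.

Under independent Poisson spiking with spatial tuning curves f_i(x), the
posterior over position for a window of length tau with spike-count
vector n is

    P(x | n)  proportional to  P(x) * prod_i f_i(x)**n_i * exp(-tau * sum_i f_i(x))

computed in log space with a uniform prior and normalized jointly over
the concatenated position bins of both tracks, so each time-bin column
sums to 1 across tracks. A small rate floor replaces zeros inside
f_i(x)**n_i only, to keep empty unsmoothed bins from forcing -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import LinearizedPosition
from .config import AnalysisConfig
from .placefields import RateMapSet
from .session import Session


@dataclass
class PosteriorMatrix:
    """Decoded probabilities over concatenated track bins x time windows."""

    probs: np.ndarray          # (n_bins_total, n_windows), columns sum to 1
    bin_centers: np.ndarray    # cm, per concatenated bin
    track_of_bin: np.ndarray   # track id per concatenated bin
    window_starts: np.ndarray  # s
    window_s: float
    unit_ids: list[int]
    counts: np.ndarray         # (n_units, n_windows)

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window_s / 2

    def track_submatrix(self, track_id: int) -> np.ndarray:
        return self.probs[self.track_of_bin == track_id]

    def track_bias(self, track_id: int) -> float:
        """Summed posterior mass of one track over the total across tracks."""
        total = self.probs.sum()
        if total <= 0:
            return np.nan
        return float(self.track_submatrix(track_id).sum() / total)

    def map_estimate(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-window argmax position and its track id."""
        idx = np.argmax(self.probs, axis=0)
        return self.bin_centers[idx], self.track_of_bin[idx]


def _stack_maps(maps: list[RateMapSet], unit_ids: list[int]):
    mats, centers, tracks = [], [], []
    for m in maps:
        missing = set(unit_ids) - set(m.rates)
        if missing:
            raise ValueError(f"units missing from maps for track {m.track_id}: {sorted(missing)[:5]}")
        mats.append(m.matrix(unit_ids))
        centers.append(m.bin_centers)
        tracks.append(np.full(m.bin_centers.size, m.track_id))
    F = np.concatenate(mats, axis=1)
    return F, np.concatenate(centers), np.concatenate(tracks)


def decode(
    counts: np.ndarray,
    maps: list[RateMapSet],
    unit_ids: list[int],
    tau: float,
    window_starts: np.ndarray | None = None,
    prior: np.ndarray | None = None,
    rate_floor_hz: float = 0.01,
) -> PosteriorMatrix:
    """Decode spike-count columns into position posteriors.

    ``counts`` is (n_units, n_windows) aligned with ``unit_ids``; ``maps``
    are unsmoothed ratemaps, one per track, sharing those units. The
    posterior is normalized per column across all tracks jointly.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    F, centers, tracks = _stack_maps(maps, unit_ids)
    if counts.shape[0] != len(unit_ids):
        raise ValueError("counts rows must match unit_ids")
    logF = np.log(np.maximum(F, rate_floor_hz))
    L = counts.T @ logF - tau * F.sum(axis=0)[None, :]   # (T, X)
    if prior is not None:
        prior = np.asarray(prior, float)
        L = L + np.log(np.maximum(prior, 1e-300))[None, :]
    L -= L.max(axis=1, keepdims=True)
    P = np.exp(L)
    P /= P.sum(axis=1, keepdims=True)
    if window_starts is None:
        window_starts = np.arange(counts.shape[1]) * tau
    return PosteriorMatrix(P.T, centers, tracks, np.asarray(window_starts, float),
                           tau, list(unit_ids), counts)


def count_spikes(
    session: Session, unit_ids: list[int], start: float, end: float, window_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping spike-count windows covering [start, end)."""
    n_win = int(np.floor((end - start) / window_s + 1e-9))
    if n_win < 1:
        raise ValueError("no decoding windows in interval")
    edges = start + np.arange(n_win + 1) * window_s
    units = {u.unit_id: u for u in session.units}
    counts = np.zeros((len(unit_ids), n_win))
    for i, uid in enumerate(unit_ids):
        st = units[uid].spike_times
        seg = st[np.searchsorted(st, start):np.searchsorted(st, edges[-1])]
        counts[i] = np.histogram(seg, bins=edges)[0]
    return counts, edges[:-1]


def decode_interval(
    session: Session,
    unit_ids: list[int],
    maps: list[RateMapSet],
    start: float,
    end: float,
    window_s: float,
    config: AnalysisConfig | None = None,
) -> PosteriorMatrix:
    config = config or AnalysisConfig()
    counts, starts = count_spikes(session, unit_ids, start, end, window_s)
    return decode(counts, maps, unit_ids, window_s, starts,
                  rate_floor_hz=config.rate_floor_hz)


@dataclass
class DecodingQC:
    median_error_cm: float
    per_epoch_error_cm: dict[str, float]
    confusion: np.ndarray       # true bin x decoded bin, occupancy-weighted counts
    n_windows: int
    passed: bool


def decoding_qc(
    session: Session,
    lins: dict[int, LinearizedPosition],
    maps: list[RateMapSet],
    unit_ids: list[int],
    epochs: dict[str, int],
    config: AnalysisConfig | None = None,
) -> DecodingQC:
    """Median decoding error during locomotion, decoded at 250-ms windows.

    ``epochs`` maps run-epoch labels to their track ids. Windows whose
    mean speed is below the locomotion threshold (reward-zone pauses) are
    excluded. A window decoded to the wrong track scores a full track
    length of error. The session passes QC when the median error is at or
    below the configured bound (15 cm).
    """
    config = config or AnalysisConfig()
    errors: list[np.ndarray] = []
    per_epoch: dict[str, float] = {}
    n_bins = maps[0].bin_centers.size
    confusion = np.zeros((n_bins, n_bins))
    total = 0
    for label, tid in epochs.items():
        start, end = session.epoch_bounds(label)
        post = decode_interval(session, unit_ids, maps, start, end,
                               config.decode_window_run_s, config)
        lin = lins[tid]
        centers_t = post.window_centers
        speed = lin.interp_speed(centers_t)
        true_pos = lin.interp_position(centers_t)
        moving = speed >= config.qc_speed_min_cms
        if not moving.any():
            continue
        est_pos, est_track = post.map_estimate()
        err = np.where(
            est_track[moving] == tid,
            np.abs(est_pos[moving] - true_pos[moving]),
            lin.track_length_cm,
        )
        errors.append(err)
        per_epoch[label] = float(np.median(err))
        # confusion over this track's bins only (correct-track windows)
        edges = maps[0].bin_edges
        tb = np.clip(np.digitize(true_pos[moving], edges) - 1, 0, n_bins - 1)
        db = np.clip(np.digitize(est_pos[moving], edges) - 1, 0, n_bins - 1)
        same = est_track[moving] == tid
        np.add.at(confusion, (tb[same], db[same]), 1)
        total += int(moving.sum())
    if not errors:
        raise ValueError("no locomotion windows to evaluate")
    all_err = np.concatenate(errors)
    med = float(np.median(all_err))
    return DecodingQC(med, per_epoch, confusion, total,
                      passed=med <= config.qc_max_median_error_cm)
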