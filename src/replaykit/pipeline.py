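"""End-to-end session analysis: behavior -> maps -> events -> metrics.

Ties the stage modules together the way a full session is processed:
clean and linearize position, classify cells, build per-exposure decoding
maps, select LFP channels, score putative sleep, detect and score replay
candidates in every epoch (first-exposure maps for PRE/RUN1/POST1,
re-exposure maps for RUN2/POST2), run the theta-sequence analysis on run
epochs, and assemble session metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import LinearizedPosition, session_behavior
from .config import AnalysisConfig
from .decoder import DecodingQC, decoding_qc
from .lfp import BandSignal, SleepMask, band_filter_hilbert, detect_putative_sleep, select_channels
from .placefields import RateMapSet, classify_units, compute_ratemaps, place_cells
from .replay import (CandidateEvent, ReplayScore, detect_candidates, label_state,
                     score_significance, split_event)
from .session import POST_EPOCHS, RUN_EPOCHS, Session
from .stats import SessionMetrics, compute_session_metrics
from .theta import (average_theta_sequences, decode_theta_windows, detect_theta_cycles,
                    lap_directional_maps)

EXPOSURE_OF_EPOCH = {"PRE": 1, "RUN1_T1": 1, "RUN1_T2": 1, "POST1": 1,
                     "RUN2_T1": 2, "RUN2_T2": 2, "POST2": 2}
_EPOCH_STREAM = {label: i for i, label in enumerate(EXPOSURE_OF_EPOCH)}


@dataclass
class SessionAnalysis:
    config: AnalysisConfig
    roster: pd.DataFrame
    lins: dict[int, LinearizedPosition]
    behavior_summaries: list
    lap_table: pd.DataFrame
    maps: dict[int, list[RateMapSet]]          # exposure -> [track1 maps, track2 maps]
    decode_units: dict[int, list[int]]         # exposure -> unit ids
    sleep_masks: dict[str, SleepMask]
    candidates: dict[str, list[CandidateEvent]]
    scores: list[ReplayScore]
    events: pd.DataFrame
    qc: DecodingQC | None
    theta: dict[str, object] = field(default_factory=dict)
    metrics: SessionMetrics | None = None


def exposure_maps(
    session: Session,
    lins: dict[int, LinearizedPosition],
    unit_ids: list[int],
    exposure: int,
    config: AnalysisConfig,
) -> list[RateMapSet]:
    """Unsmoothed decoding maps (10-cm bins) for one exposure, both tracks."""
    labels = {1: ["RUN1_T1", "RUN1_T2"], 2: ["RUN2_T1", "RUN2_T2"]}[exposure]
    maps = []
    for label in labels:
        tid = RUN_EPOCHS[label]
        maps.append(compute_ratemaps(
            session, lins[tid], unit_ids, [session.epoch_bounds(label)],
            bin_size_cm=config.bin_size_decode_cm,
            speed_window_cms=(config.ratemap_speed_min_cms, config.ratemap_speed_max_cms),
        ))
    return maps


def events_dataframe(scores: list[ReplayScore]) -> pd.DataFrame:
    rows = []
    for sc in scores:
        ev = sc.event
        row = {
            "start_s": ev.start_s, "end_s": ev.end_s, "duration_s": ev.duration_s,
            "epoch": ev.epoch, "n_units": len(ev.participating_units),
            "peak_mua_z": ev.peak_mua_z, "peak_ripple_z": ev.peak_ripple_z,
            "track": sc.assigned_track if sc.assigned_track is not None else np.nan,
            "state": sc.state, "split": sc.split, "discarded": sc.discarded,
        }
        for tid, ts in sc.per_track.items():
            row[f"r_t{tid}"] = ts.r
            row[f"bias_t{tid}"] = ts.bias
            row[f"p_spike_t{tid}"], row[f"p_field_t{tid}"], row[f"p_pos_t{tid}"] = ts.p_values
            row[f"sig_t{tid}"] = ts.significant
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_session(
    session: Session,
    config: AnalysisConfig | None = None,
    n_shuffles: int | None = None,
    theta_n_shuffles: int | None = None,
    run_theta: bool = True,
    run_qc: bool = True,
    epochs: list[str] | None = None,
) -> SessionAnalysis:
    """Run the full replay pipeline on one session.

    ``n_shuffles`` / ``theta_n_shuffles`` override the configured shuffle
    count (useful for quick passes); ``epochs`` restricts replay detection
    to a subset of epoch labels.
    """
    config = config or AnalysisConfig()
    import dataclasses
    import logging

    logging.getLogger("replaykit").info(
        "analyze_session seed=%d config=%s", config.seed, dataclasses.asdict(config)
    )
    summaries, lap_table, lins = session_behavior(session, config)
    roster = classify_units(session, lins, config)
    decode_units: dict[int, list[int]] = {}
    maps: dict[int, list[RateMapSet]] = {}
    for exposure in (1, 2):
        uids = sorted(set(place_cells(roster, 1)) | set(place_cells(roster, 2)))
        decode_units[exposure] = uids
        maps[exposure] = exposure_maps(session, lins, uids, exposure, config)

    channels = select_channels(session.lfp, config)
    ripple_trace = next(tr for tr in session.lfp if tr.channel_id == channels["ripple"])
    ripple = band_filter_hilbert(ripple_trace, config.ripple_band_hz, config.filter_order)
    theta_trace = next(tr for tr in session.lfp if tr.channel_id == channels["theta"])

    # global 2-D speed (identical across track linearizations)
    any_lin = next(iter(lins.values()))
    speed_times, speed = any_lin.time_s, any_lin.speed_cms

    sleep_masks: dict[str, SleepMask] = {}
    for label in ["PRE"] + POST_EPOCHS:
        try:
            bounds = session.epoch_bounds(label)
        except KeyError:
            continue
        sleep_masks[label] = detect_putative_sleep(
            speed_times, speed, session.units, bounds,
            config.sleep_bin_s, config.sleep_speed_cms, config.sleep_mua_z,
        )

    wanted = epochs or list(EXPOSURE_OF_EPOCH)
    candidates: dict[str, list[CandidateEvent]] = {}
    scores: list[ReplayScore] = []
    for label in wanted:
        try:
            bounds = session.epoch_bounds(label)
        except KeyError:
            continue
        cands = detect_candidates(session, ripple, speed_times, speed, bounds,
                                  label, config)
        candidates[label] = cands
        exposure = EXPOSURE_OF_EPOCH[label]
        for i, ev in enumerate(cands):
            rng = np.random.default_rng([config.seed, _EPOCH_STREAM[label], i])
            sc = score_significance(session, ev, maps[exposure],
                                    decode_units[exposure], config, rng,
                                    n_shuffles=n_shuffles)
            if sc.assigned_track is None:
                halves = split_event(session, ev, config)
                best = None
                for half in halves:
                    hs = score_significance(session, half, maps[exposure],
                                            decode_units[exposure], config, rng,
                                            alpha=config.alpha_split,
                                            n_shuffles=n_shuffles)
                    hs.split = True
                    if hs.assigned_track is not None:
                        best = hs if best is None else best
                if best is not None:
                    sc = best
            if sc.assigned_track is not None:
                epoch_track = RUN_EPOCHS.get(label)
                sc.state = label_state(sc, label, epoch_track, sleep_masks.get(label))
            scores.append(sc)
    events = events_dataframe(scores)

    qc = None
    if run_qc:
        qc = decoding_qc(session, lins, maps[2], decode_units[2],
                         {"RUN2_T1": 1, "RUN2_T2": 2}, config)

    theta_results: dict[str, object] = {}
    theta_counts: dict[str, tuple[int, int]] = {}
    if run_theta:
        theta_band = band_filter_hilbert(theta_trace, config.theta_band_hz, config.filter_order)
        for label, tid in RUN_EPOCHS.items():
            try:
                bounds = session.epoch_bounds(label)
            except KeyError:
                continue
            cycles = detect_theta_cycles(theta_band, lins[tid], bounds, config)
            uids = place_cells(roster, tid)
            laps = lap_table[lap_table["epoch"] == label]
            if not cycles or not uids or laps.empty:
                theta_counts[label] = (0, len(cycles))
                continue
            lmaps = lap_directional_maps(session, lins[tid], laps, uids, config)
            decoded = decode_theta_windows(session, cycles, laps, lmaps, uids, config)
            if not decoded:
                theta_counts[label] = (0, len(cycles))
                continue
            res = average_theta_sequences(
                decoded, config, score=True,
                rng=np.random.default_rng([config.seed, 77, _EPOCH_STREAM[label]]),
                n_shuffles=theta_n_shuffles, session=session,
            )
            theta_results[label] = res
            theta_counts[label] = (res.n_significant, len(cycles))

    cand_counts = {label: len(c) for label, c in candidates.items() if label in RUN_EPOCHS}
    metrics = compute_session_metrics(events, sleep_masks, summaries,
                                      theta_counts, cand_counts, config)
    return SessionAnalysis(config, roster, lins, summaries, lap_table, maps,
                           decode_units, sleep_masks, candidates, scores, events,
                           qc, theta_results, metrics)
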