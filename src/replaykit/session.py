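"""Session container and on-disk format.

A recording session holds sorted single units (spike times plus a waveform
half-width used for cell-type classification), 2-D position samples, one or
more LFP traces, an epoch table covering the seven-stage two-track protocol
(PRE, RUN1_T1, RUN1_T2, POST1, RUN2_T1, RUN2_T2, POST2), and the geometry
of the two linear tracks.

On disk a session is a directory with a JSON manifest (``session.json``),
TSV spike and position tables, and an HDF5 file of LFP traces. Times are
seconds on a session clock starting at 0, positions are cm, and intervals
are half-open ``[start, end)`` throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

EPOCH_ORDER = ["PRE", "RUN1_T1", "RUN1_T2", "POST1", "RUN2_T1", "RUN2_T2", "POST2"]
RUN_EPOCHS = {"RUN1_T1": 1, "RUN1_T2": 2, "RUN2_T1": 1, "RUN2_T2": 2}
POST_EPOCHS = ["POST1", "POST2"]


@dataclass
class Unit:
    unit_id: int
    spike_times: np.ndarray          # s, sorted ascending
    half_width_us: float             # waveform half-width half-max
    mean_rate_hz: float              # session-wide mean rate

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class LfpTrace:
    channel_id: int
    sample_rate_hz: float
    samples: np.ndarray              # uV
    start_s: float = 0.0

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class Track:
    track_id: int
    length_cm: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]

    @property
    def axis(self) -> np.ndarray:
        v = np.asarray(self.end_xy, float) - np.asarray(self.start_xy, float)
        n = float(np.hypot(*v))
        if n == 0:
            raise ValueError("degenerate track geometry: zero-length axis")
        return v / n


@dataclass
class Session:
    units: list[Unit]
    position: pd.DataFrame           # columns time_s, x_cm, y_cm
    lfp: list[LfpTrace]
    epochs: pd.DataFrame             # columns label, start_s, end_s
    tracks: dict[int, Track]

    def validate(self) -> "Session":
        for u in self.units:
            if u.spike_times.size and np.any(np.diff(u.spike_times) < 0):
                raise ValueError(f"invalid spike train: unit {u.unit_id} not sorted")
        ep = self.epochs
        if list(ep.columns[:3]) != ["label", "start_s", "end_s"]:
            raise ValueError("invalid epochs: bad columns")
        if np.any(ep["end_s"].values <= ep["start_s"].values):
            raise ValueError("invalid epochs: non-positive duration")
        starts, ends = ep["start_s"].values, ep["end_s"].values
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("invalid epochs: overlapping or unordered")
        span = (float(ep["start_s"].min()), float(ep["end_s"].max()))
        for u in self.units:
            if u.spike_times.size and (
                u.spike_times[0] < span[0] - 1e-6 or u.spike_times[-1] > span[1] + 1e-6
            ):
                raise ValueError(f"invalid spike train: unit {u.unit_id} outside session span")
        return self

    def epoch_bounds(self, label: str) -> tuple[float, float]:
        row = self.epochs[self.epochs["label"] == label]
        if row.empty:
            raise KeyError(f"no epoch {label!r}")
        return float(row["start_s"].iloc[0]), float(row["end_s"].iloc[0])

    def epoch_of_time(self, t: float) -> str | None:
        for _, row in self.epochs.iterrows():
            if row["start_s"] <= t < row["end_s"]:
                return str(row["label"])
        return None

    def spikes_in(self, unit: Unit, start: float, end: float) -> np.ndarray:
        st = unit.spike_times
        return st[np.searchsorted(st, start):np.searchsorted(st, end)]


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory (manifest + TSVs + LFP HDF5). Bit-stable."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for u in session.units:
        rows.append(pd.DataFrame({"unit_id": u.unit_id, "time_s": u.spike_times}))
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False, float_format="%.17g")
    session.position.to_csv(
        path / "position.tsv", sep="\t", index=False, float_format="%.17g"
    )
    with h5py.File(path / "lfp.h5", "w") as f:
        for tr in session.lfp:
            d = f.create_dataset(f"channel_{tr.channel_id}", data=np.asarray(tr.samples, np.float32))
            d.attrs["sample_rate_hz"] = tr.sample_rate_hz
            d.attrs["start_s"] = tr.start_s
    manifest = {
        "files": {"spikes": "spikes.tsv", "position": "position.tsv", "lfp": "lfp.h5"},
        "units": [
            {
                "unit_id": u.unit_id,
                "half_width_us": u.half_width_us,
                "mean_rate_hz": u.mean_rate_hz,
            }
            for u in session.units
        ],
        "epochs": [
            {"label": r["label"], "start_s": float(r["start_s"]), "end_s": float(r["end_s"])}
            for _, r in session.epochs.iterrows()
        ],
        "tracks": [
            {
                "track_id": t.track_id,
                "length_cm": t.length_cm,
                "start_xy": list(t.start_xy),
                "end_xy": list(t.end_xy),
            }
            for t in session.tracks.values()
        ],
        "lfp_channels": [
            {"channel_id": tr.channel_id, "sample_rate_hz": tr.sample_rate_hz}
            for tr in session.lfp
        ],
    }
    with open(path / "session.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    mpath = path / "session.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing component: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if "epochs" not in manifest:
        raise ValueError("missing component: manifest has no epochs")
    for key in ("spikes", "position", "lfp"):
        if not (path / manifest["files"][key]).exists():
            raise FileNotFoundError(f"missing component: {manifest['files'][key]}")
    spikes = pd.read_csv(path / manifest["files"]["spikes"], sep="\t")
    units = []
    for meta in manifest["units"]:
        st = spikes.loc[spikes["unit_id"] == meta["unit_id"], "time_s"].values
        units.append(
            Unit(
                unit_id=int(meta["unit_id"]),
                spike_times=st,
                half_width_us=float(meta["half_width_us"]),
                mean_rate_hz=float(meta["mean_rate_hz"]),
            )
        )
    position = pd.read_csv(path / manifest["files"]["position"], sep="\t")
    lfp = []
    with h5py.File(path / manifest["files"]["lfp"], "r") as f:
        for meta in manifest["lfp_channels"]:
            d = f[f"channel_{meta['channel_id']}"]
            lfp.append(
                LfpTrace(
                    channel_id=int(meta["channel_id"]),
                    sample_rate_hz=float(d.attrs["sample_rate_hz"]),
                    samples=d[...].astype(np.float64),
                    start_s=float(d.attrs.get("start_s", 0.0)),
                )
            )
    epochs = pd.DataFrame(manifest["epochs"])[["label", "start_s", "end_s"]]
    tracks = {
        int(t["track_id"]): Track(
            track_id=int(t["track_id"]),
            length_cm=float(t["length_cm"]),
            start_xy=tuple(t["start_xy"]),
            end_xy=tuple(t["end_xy"]),
        )
        for t in manifest["tracks"]
    }
    return Session(units=units, position=position, lfp=lfp, epochs=epochs, tracks=tracks).validate()
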