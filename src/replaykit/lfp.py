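"""LFP spectral channel selection, band filtering, MUA traces, and
putative-sleep scoring.

Channel roles are assigned from Welch power spectra (2-s windows, 50%
overlap): the channels with the most theta (4-12 Hz) and ripple
(125-300 Hz) power, plus the channel with the largest difference in
normalized theta-to-ripple power. Band signals are zero-phase Butterworth
filtered (forward-reverse) with instantaneous phase/amplitude from the
Hilbert transform.

Putative sleep is scored in 60-s bins: mean speed below 4 cm/s together
with above-baseline multi-unit activity (z > 0) of the most active third
of units. An LFP-based control labels awake/NREM/REM from z-scored theta
power and theta/delta ratio and reports agreement with the primary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisConfig
from .session import LfpTrace, Session, Unit


# --------------------------------------------------------------------------
# spectra and band signals


def band_power(trace: LfpTrace, band: tuple[float, float], psd_window_s: float = 2.0):
    """Integrated Welch PSD power in a band, plus total power."""
    nper = int(psd_window_s * trace.sample_rate_hz)
    freqs, psd = signal.welch(
        trace.samples, fs=trace.sample_rate_hz, nperseg=nper, noverlap=nper // 2
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel])), float(np.trapezoid(psd, freqs))


def select_channels(
    lfp: list[LfpTrace], config: AnalysisConfig | None = None
) -> dict[str, int]:
    """Pick theta, ripple, and theta-ripple-contrast channels by band power."""
    config = config or AnalysisConfig()
    if not lfp:
        raise ValueError("no LFP channels")
    theta_p, ripple_p, contrast = {}, {}, {}
    for tr in lfp:
        tp, total = band_power(tr, config.theta_band_hz, config.psd_window_s)
        rp, _ = band_power(tr, config.ripple_band_hz, config.psd_window_s)
        theta_p[tr.channel_id] = tp
        ripple_p[tr.channel_id] = rp
        contrast[tr.channel_id] = tp / total - rp / total
    return {
        "theta": max(theta_p, key=theta_p.get),
        "ripple": max(ripple_p, key=ripple_p.get),
        "contrast": max(contrast, key=contrast.get),
    }


@dataclass
class BandSignal:
    channel_id: int
    band: tuple[float, float]
    sample_rate_hz: float
    start_s: float
    filtered: np.ndarray
    phase: np.ndarray        # rad, in [-pi, pi)
    amplitude: np.ndarray    # >= 0

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.filtered.size) / self.sample_rate_hz

    def smoothed_amplitude(self, window_s: float) -> np.ndarray:
        n = max(1, int(round(window_s * self.sample_rate_hz)))
        kernel = np.ones(n) / n
        padded = np.pad(self.amplitude, (n // 2, n - 1 - n // 2), mode="edge")
        return np.convolve(padded, kernel, mode="valid")


def band_filter_hilbert(
    trace: LfpTrace, band: tuple[float, float], order: int = 4
) -> BandSignal:
    """Zero-phase band-pass filter plus analytic-signal phase/amplitude.

    Filtering runs forward and reverse (``sosfiltfilt``) to avoid phase
    delays; the Hilbert transform of the filtered trace gives the
    instantaneous phase and amplitude.
    """
    nyq = trace.sample_rate_hz / 2.0
    if band[1] >= nyq:
        raise ValueError(f"sample rate {trace.sample_rate_hz} too low for band {band}")
    sos = signal.butter(order, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(trace.samples, float))
    analytic = signal.hilbert(filt)
    phase = np.angle(analytic)
    amplitude = np.abs(analytic)
    return BandSignal(trace.channel_id, band, trace.sample_rate_hz, trace.start_s,
                      filt, phase, amplitude)


# --------------------------------------------------------------------------
# multi-unit activity


def mua_trace(
    units: list[Unit],
    start: float,
    end: float,
    bin_s: float = 0.001,
    smooth_sd_s: float = 0.005,
    top_third: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Population spike histogram (1-ms bins, 5-ms Gaussian smoothing), z-scored.

    With ``top_third`` only the most active third of units (by total spike
    count in the window) contribute, the noise-robust variant used for
    sleep scoring. Returns ``(bin centers, z)``; z-scoring is relative to
    the full ``[start, end)`` window.
    """
    pool = units
    if top_third:
        counts = [(u, session_count(u, start, end)) for u in units]
        counts.sort(key=lambda t: -t[1])
        pool = [u for u, _ in counts[: max(1, len(counts) // 3)]]
    edges = np.arange(start, end + bin_s, bin_s)
    hist = np.zeros(edges.size - 1)
    for u in pool:
        st = u.spike_times
        seg = st[np.searchsorted(st, start):np.searchsorted(st, end)]
        if seg.size:
            hist += np.histogram(seg, bins=edges)[0]
    smoothed = gaussian_filter1d(hist, sigma=smooth_sd_s / bin_s)
    sd = smoothed.std()
    z = (smoothed - smoothed.mean()) / sd if sd > 0 else np.zeros_like(smoothed)
    centers = edges[:-1] + bin_s / 2
    return centers, z


def session_count(u: Unit, start: float, end: float) -> int:
    st = u.spike_times
    return int(np.searchsorted(st, end) - np.searchsorted(st, start))


# --------------------------------------------------------------------------
# putative sleep


@dataclass
class SleepMask:
    """1-min sleep flags for one rest epoch plus the cumulative sleep clock."""

    bins: pd.DataFrame  # bin_start_s, bin_end_s, speed_ok, mua_ok, sleep, cum_sleep_s
    bin_s: float

    def is_sleep_at(self, t: float) -> bool:
        b = self.bins
        row = b[(b["bin_start_s"] <= t) & (t < b["bin_end_s"])]
        return bool(row["sleep"].iloc[0]) if not row.empty else False

    @property
    def total_sleep_s(self) -> float:
        return float(self.bins["sleep"].sum() * self.bin_s)

    def sleep_intervals(self) -> list[tuple[float, float]]:
        iv = []
        for _, r in self.bins[self.bins["sleep"]].iterrows():
            if iv and abs(iv[-1][1] - r["bin_start_s"]) < 1e-9:
                iv[-1] = (iv[-1][0], float(r["bin_end_s"]))
            else:
                iv.append((float(r["bin_start_s"]), float(r["bin_end_s"])))
        return iv

    def first_cumulative_window(self, window_s: float = 1800.0):
        """Sleep intervals making up the first ``window_s`` of cumulative sleep.

        Returns ``(intervals, attained seconds)``; the last interval is
        truncated so the total is exactly ``window_s`` when enough sleep
        exists.
        """
        iv, acc = [], 0.0
        for a, b in self.sleep_intervals():
            if acc >= window_s:
                break
            take = min(b - a, window_s - acc)
            iv.append((a, a + take))
            acc += take
        return iv, acc


def detect_putative_sleep(
    speed_times: np.ndarray,
    speed: np.ndarray,
    units: list[Unit],
    epoch: tuple[float, float],
    bin_s: float = 60.0,
    speed_thresh_cms: float = 4.0,
    mua_thresh_z: float = 0.0,
) -> SleepMask:
    """Score 1-min bins of a rest epoch as putative sleep.

    A bin is sleep when its mean speed is below ``speed_thresh_cms`` and
    the mean z-scored MUA of the most active third of units exceeds
    ``mua_thresh_z``.
    """
    start, end = epoch
    if end - start < bin_s:
        raise ValueError("epoch shorter than one sleep bin")
    mua_t, mua_z = mua_trace(units, start, end, top_third=True)
    edges = np.arange(start, end + 1e-9, bin_s)
    if edges[-1] < end - 1e-6:
        edges = np.append(edges, end)
    rows = []
    cum = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < bin_s - 1e-6:
            break  # drop trailing partial bin
        sp = speed[(speed_times >= a) & (speed_times < b)]
        mz = mua_z[(mua_t >= a) & (mua_t < b)]
        speed_ok = bool(sp.size and sp.mean() < speed_thresh_cms)
        mua_ok = bool(mz.size and mz.mean() > mua_thresh_z)
        sleep = speed_ok and mua_ok
        cum += bin_s if sleep else 0.0
        rows.append({"bin_start_s": a, "bin_end_s": b, "speed_ok": speed_ok,
                     "mua_ok": mua_ok, "sleep": sleep, "cum_sleep_s": cum})
    return SleepMask(pd.DataFrame(rows), bin_s)


def lfp_sleep_control(
    theta_trace: LfpTrace,
    delta_trace: LfpTrace,
    speed_times: np.ndarray,
    speed: np.ndarray,
    epoch: tuple[float, float],
    sleep_mask: SleepMask,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """LFP-based awake/NREM/REM labeling and agreement with the MUA mask.

    Awake: theta-power z > 0.5 and speed > 4 cm/s. NREM: theta z < 0.5,
    speed < 4, theta/delta-ratio z > 0.5. REM: theta z > 0.5, speed < 4,
    ratio z > 0.5. NREM and REM are merged into a sleep mask whose
    per-bin Pearson correlation with the primary mask is returned.
    """
    config = config or AnalysisConfig()
    if theta_trace is None or delta_trace is None:
        raise ValueError("no LFP")
    start, end = epoch
    th = band_filter_hilbert(theta_trace, config.theta_band_hz, config.filter_order)
    de = band_filter_hilbert(delta_trace, config.delta_band_hz, config.filter_order)
    t = th.times()
    sel = (t >= start) & (t < end)
    power_t = th.amplitude[sel] ** 2
    power_d = de.amplitude[sel] ** 2
    tt = t[sel]
    bins = sleep_mask.bins
    rows = []
    z_thr = config.sleep_state_z
    theta_bin = np.array([power_t[(tt >= a) & (tt < b)].mean()
                          for a, b in zip(bins["bin_start_s"], bins["bin_end_s"])])
    ratio_bin = np.array([
        power_t[(tt >= a) & (tt < b)].mean() / max(power_d[(tt >= a) & (tt < b)].mean(), 1e-12)
        for a, b in zip(bins["bin_start_s"], bins["bin_end_s"])
    ])
    theta_z = (theta_bin - theta_bin.mean()) / (theta_bin.std() + 1e-12)
    ratio_z = (ratio_bin - ratio_bin.mean()) / (ratio_bin.std() + 1e-12)
    for i, (_, r) in enumerate(bins.iterrows()):
        sp = speed[(speed_times >= r["bin_start_s"]) & (speed_times < r["bin_end_s"])]
        v = float(sp.mean()) if sp.size else 0.0
        if theta_z[i] > z_thr and v > config.sleep_speed_cms:
            label = "awake"
        elif theta_z[i] < z_thr and v < config.sleep_speed_cms and ratio_z[i] > z_thr:
            label = "NREM"
        elif theta_z[i] > z_thr and v < config.sleep_speed_cms and ratio_z[i] > z_thr:
            label = "REM"
        else:
            label = "awake"
        rows.append({"bin_start_s": r["bin_start_s"], "label": label,
                     "theta_z": theta_z[i], "ratio_z": ratio_z[i], "speed": v})
    labels = pd.DataFrame(rows)
    lfp_sleep = labels["label"].isin(["NREM", "REM"]).to_numpy(float)
    mua_sleep = bins["sleep"].to_numpy(float)
    if lfp_sleep.std() == 0 or mua_sleep.std() == 0:
        agreement = 1.0 if np.array_equal(lfp_sleep, mua_sleep) else 0.0
    else:
        agreement = float(np.corrcoef(lfp_sleep, mua_sleep)[0, 1])
    return labels, agreement
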