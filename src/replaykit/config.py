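"""Analysis configuration: every numeric threshold used by the pipeline.

Defaults are the values used throughout the analysis; any subset can be
overridden from a YAML file with :func:`load_config`. Unknown keys raise,
so typos in config files fail loudly instead of silently keeping defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("replaykit")


@dataclass(frozen=True)
class AnalysisConfig:
    """Numeric parameters of the analysis pipeline.

    Units are cm, seconds, Hz and microseconds as indicated by each
    field name. Thresholds follow the standard sharp-wave-ripple /
    replay detection workflow for rodent linear-track recordings.
    """

    # -- position cleaning / behavior --
    position_jump_limit_cm: float = 40.0     # max distance between consecutive samples
    position_speed_limit_cms: float = 100.0  # max implied speed between samples
    speed_smooth_s: float = 0.4              # moving-average window on speed
    immobility_speed_cms: float = 4.0        # below this the animal counts as immobile
    end_zone_cm: float = 20.0                # reward zone at each track end

    # -- ratemaps / cell classification --
    bin_size_decode_cm: float = 10.0         # position bin for Bayesian decoding
    bin_size_fine_cm: float = 2.0            # fine bins for display / theta maps
    classification_bin_cm: float = 10.0      # unsmoothed map used for the >1 Hz rule
    ratemap_smooth_sd_bins: float = 1.0      # Gaussian sd for smoothed maps
    ratemap_speed_min_cms: float = 4.0       # spikes kept when 4 <= speed <= 50 cm/s
    ratemap_speed_max_cms: float = 50.0
    principal_min_hwhm_us: float = 500.0     # waveform half-width half-max
    principal_max_rate_hz: float = 5.0       # session-wide mean rate ceiling
    place_min_peak_hz: float = 1.0           # unsmoothed-map peak to call a place cell

    # -- decoding --
    decode_window_run_s: float = 0.25
    decode_window_replay_s: float = 0.02
    decode_window_theta_s: float = 0.01
    rate_floor_hz: float = 0.01              # floor inside f_i(x)**n_i only
    qc_max_median_error_cm: float = 15.0     # session discarded above this
    qc_speed_min_cms: float = 5.0            # QC windows must be locomotion windows

    # -- LFP bands --
    theta_band_hz: tuple[float, float] = (4.0, 12.0)
    ripple_band_hz: tuple[float, float] = (125.0, 300.0)
    delta_band_hz: tuple[float, float] = (1.0, 4.0)
    filter_order: int = 4
    psd_window_s: float = 2.0                # Welch window, 50% overlap

    # -- candidate event detection --
    mua_bin_s: float = 0.001
    mua_smooth_sd_s: float = 0.005
    mua_z_threshold: float = 3.0
    mua_burst_max_s: float = 0.3             # cap on the supra-threshold burst core
    ripple_z_threshold: float = 3.0
    ripple_smooth_s: float = 0.1             # moving average on ripple amplitude
    merge_gap_s: float = 0.05
    event_speed_max_cms: float = 5.0         # events during faster movement excluded
    event_min_units: int = 5
    event_min_duration_s: float = 0.1
    event_max_duration_s: float = 0.75

    # -- significance testing --
    n_shuffles: int = 1000
    alpha: float = 0.05
    alpha_split: float = 0.025               # halves of split events
    bias_threshold: float = 0.6              # Bayesian bias needed to assign a track

    # -- putative sleep --
    sleep_bin_s: float = 60.0
    sleep_speed_cms: float = 4.0
    sleep_mua_z: float = 0.0
    sleep_window_s: float = 1800.0           # first 30 min of cumulative sleep
    sleep_state_z: float = 0.5               # theta / ratio z threshold (LFP control)

    # -- theta sequences --
    theta_cycle_min_s: float = 0.08
    theta_cycle_max_s: float = 0.2
    theta_amp_fraction: float = 0.25         # extrema threshold vs median amplitude
    theta_speed_min_cms: float = 5.0
    theta_min_active_units: int = 2
    theta_bin_cm: float = 2.0                # bin size of theta decoding maps
    theta_center_cm: float = 40.0            # posterior centered on +/- this span

    # -- decoding-free SWR classification --
    selective_margin: float = 0.2

    seed: int = 0


def load_config(path: str | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Missing keys take defaults; unknown keys raise ``ValueError``. The
    fully resolved configuration is echoed to the package logger so every
    run records the thresholds and seed it used.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file must be a mapping, got {type(loaded)}")
            data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("theta_band_hz", "ripple_band_hz", "delta_band_hz"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    cfg = AnalysisConfig(**data)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg
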