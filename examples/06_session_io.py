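"""Write a session to disk and read it back.

Sessions live in a directory: a JSON manifest with epochs, tracks, unit
metadata and sample rates; TSV spike and position tables; and an HDF5
file of LFP traces. Analysis thresholds load from YAML with unknown keys
rejected.
"""

import tempfile
from pathlib import Path

from replaykit import (SyntheticConfig, load_config, read_session, simulate_session,
                       write_session)

session, truth = simulate_session(
    SyntheticConfig(seed=3, n_cells_per_track=10, n_laps_t1=2, n_laps_t2=1,
                    sleep_duration_s=300.0, run2_duration_s=100.0))

with tempfile.TemporaryDirectory() as d:
    out = Path(d) / "session"
    write_session(session, out)
    print("wrote:", sorted(p.name for p in out.iterdir()))
    back = read_session(out)
    print(f"read back {len(back.units)} units, "
          f"{len(back.position)} position samples, {len(back.epochs)} epochs")

    cfg_file = Path(d) / "analysis.yaml"
    cfg_file.write_text("ripple_z_threshold: 2.5\nn_shuffles: 500\n")
    cfg = load_config(str(cfg_file))
    print(f"config: ripple z threshold {cfg.ripple_z_threshold}, "
          f"{cfg.n_shuffles} shuffles, all other thresholds at defaults")
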