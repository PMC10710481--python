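# Methods

This note documents the models, thresholds and design choices behind
`replaykit`, and what the synthetic sessions do and do not establish
about real recordings.

## Session model and units

A session is a single clock starting at 0 s, with seven contiguous
epochs: PRE, RUN1_T1, RUN1_T2, POST1, RUN2_T1, RUN2_T2, POST2. Times
are seconds, positions centimeters, rates hertz, waveform widths
microseconds. All intervals are half-open `[start, end)`, which makes
event merging and epoch concatenation unambiguous. Sessions serialize
to a directory (JSON manifest, TSV spikes/position, HDF5 LFP); every
analysis entry point takes an `AnalysisConfig` whose defaults are the
thresholds listed below, loadable from YAML with unknown keys rejected.

## Behavior

Tracking is cleaned per epoch (the animal is carried between the rest
box and the tracks, so an epoch-boundary relocation is not a glitch):
samples more than 40 cm or 100 cm/s from the last accepted sample are
removed and linearly interpolated, anchored on the last good sample so
a burst of reflection points is dropped as a block. Cleaned 2-D
positions project onto each track's axis; speed is a centered
difference smoothed with a 0.4-s moving average before any
thresholding (the 25-Hz derivative is otherwise too noisy for a 4-cm/s
immobility cut; the window is a config key). A lap is one full
out-and-back traversal between the 20-cm reward end zones, counted
from the end-zone visit sequence, which makes the count invariant to
speed-profile changes that preserve visit order.

## Place cells and maps

Principal cells: waveform half-width half-max > 500 µs and session-wide
mean rate < 5 Hz. Place cells per track: principal, with an unsmoothed
ratemap peak > 1 Hz from spikes speed-filtered to 4–50 cm/s. The
classification map uses the 10-cm decoding bins (the finer 2-cm
maps are for display); ratemaps are spike histograms divided by dwell
time, zero-occupancy bins marked NaN. Smoothed variants (Gaussian,
sd = 1 bin) exist only for display and theta decoding; Bayesian
decoding of behavior and replay always uses unsmoothed 10-cm maps.
Remapping is quantified by per-position-bin Pearson correlation of
population rate vectors between two map sets; the null permutes unit
identities — the minimal exchangeability null given that the
comparison is between matched unit sets.

## Decoding

The Poisson population decoder is evaluated in log space; a 0.01-Hz
floor replaces zeros only inside the `f_i(x)^{n_i}` product (empty
unsmoothed bins would otherwise contribute −∞), while the
`exp(−τ Σ f)` term uses raw rates. The prior is uniform; the
normalization constant is per time window, jointly over both tracks'
concatenated bins, so a window's posterior is a probability
distribution over "where on which track". Map selection follows the
exposure: first-exposure maps decode PRE, RUN1 and POST1; re-exposure
maps decode RUN2 and POST2. Session QC decodes the re-exposure epochs
in 250-ms windows and takes the median |argmax − true| over windows
with mean speed ≥ 5 cm/s — reward-zone pauses contain awake replay
rather than locomotion and are not a test of position reconstruction.
A window whose argmax lands on the wrong track scores a full track
length. The pass bound is 15 cm.

## Replay detection and scoring

MUA is the 1-ms population spike histogram smoothed with a 5-ms
Gaussian and z-scored per epoch (an epoch-level baseline avoids
leaking running activity into rest epochs). Bursts exceed z = 3 with a
supra-threshold core no longer than 300 ms; event boundaries extend
outward to the nearest z ≤ 0 samples, the burst/quiescence boundary.
Events also need ripple-band (125–300 Hz) amplitude — Hilbert envelope
smoothed with a 0.1-s moving average, z-scored per epoch — above z = 3.
Events within 50 ms merge; events during movement (> 5 cm/s) are
excluded; survivors need ≥ 5 active units (≥ 1 spike in the window)
and 100–750 ms duration, which guarantees at least five 20-ms decoding
bins.

The sequence score is the weighted correlation of the event's
single-track posterior sub-matrix. Because forward and reverse
replay of the same trajectory differ only in the sign of r, the
significance score is |r|, compared against |r| of each null — a
direction-agnostic two-sided test. The three nulls are: circular shift
of each unit's spike-count vector in time (re-decoded), circular shift
of each unit's ratemap within its track's bins (re-decoded), and
independent circular shift of each time bin's posterior within the
track's bins. An event is significant for a track only when its score
exceeds the 95th percentile (97.5th for split halves) of all three
distributions; permutation p-values `(1 + #{null ≥ obs}) / (1 + S)`
are reported alongside. Defaults: 1000 shuffles, α = 0.05, shuffle RNG
seeded per (config seed, epoch, event index).

Track assignment: the significant track, or for multi-track events the
one with the larger Bayesian bias (its posterior mass over the total);
every assignment additionally requires bias > 0.6, a slight superset
of applying the bias rule to multi-track events only (single-track
significant events essentially always clear it). Candidates that fail
are split at the MUA minimum within their middle third — ties on a
minimum plateau break to the plateau's middle, so a flat middle third
splits at the event center — and halves meeting the candidate criteria
are re-scored at α = 0.025. Assigned events in rest epochs are labeled
sleep or rest by the 1-min putative-sleep bin containing them; events
during running are awake-local or awake-remote by whether the decoded
track matches the current one.

The decoding-free control classifies candidate SWRs by selective-cell
participation: the fraction of each track's track-selective place
cells active in the event, labeling when one fraction exceeds the
other by more than 0.20 (normalizing by population size handles
unequal selective-cell counts). Dual-track cells then contribute
per-cell firing-rate and participation differences between the two
event classes per epoch group.

## Putative sleep

A 1-min bin of a rest epoch is putative sleep when mean speed
< 4 cm/s and the z-scored MUA of the most active third of units (by
spike count in the epoch) exceeds 0. The cumulative sleep clock
supports extracting exactly the first 30 min of cumulative sleep,
truncating the final interval. The LFP control labels bins
awake/NREM/REM from z-scored theta power and theta/delta ratio with
the ±0.5 thresholds; the printed NREM and REM rules differ only in
the sign of the theta-power criterion (which is contradictory as
stated) — both are implemented as printed, and since the two classes
are merged before comparison with the MUA-based mask, the
contradiction does not affect the agreement score (per-bin Pearson
correlation of the two sleep masks).

## Theta sequences

Cycles come from a peak–trough alternation scan on the theta-band
(4–12 Hz) zero-phase-filtered LFP: local extrema below 25% of the
median instantaneous amplitude are ignored, consecutive same-type
extrema collapse to the larger, and cycles run trough to trough.
Cycles are kept at speed ≥ 5 cm/s, outside the 20-cm reward zones,
with 80–200 ms duration. Each cycle spans one 2π phase window; since
unwrapped phase is monotone in time, assigning spikes by interpolated
phase within the window equals taking spikes in the cycle's time span.
Cycles are decoded in 10-ms windows with the smoothed directional
ratemaps of their own lap at 2-cm bins — decoding bins an order finer
than the replay maps so the ±40-cm position-centered frame has usable
resolution. Cycles with < 2 active units are skipped. Posteriors are
re-registered on the animal's position, the inbound direction is
mirrored so "ahead" is positive, and cycles average element-wise.
Scoring uses the signed weighted correlation of the
direction-rectified posterior (theta sweeps are forward), against
spike-train circular shift (re-decoded), per-time-bin position
circular shift, and per-position-bin circular shift along the
time/phase axis — the last disrupts the phase domain while keeping the
position–probability relationship. The session's theta-sequence count
is the number of significant cycles.

## Statistics

Sleep replay rate: events of a track labeled sleep inside the first
30 min of cumulative sleep, divided by that window (when less sleep is
attained the available time is used and the row flagged). Rest replay
rate divides by non-sleep rest-epoch time; awake local replay rate by
immobile time on the track. The cumulative bias trace is the running
(track 1 − track 2) sleep-event count per sleep minute; its final
value equals the total count difference by construction. The decay
slope is the OLS slope of per-10-min-bin replay rate against
cumulative sleep time. Simple regressions are OLS with R² and
two-sided p; the mixed model is a random-intercept (animal) linear
model on z-scored response and predictors, with Wald 95% intervals and
significance = interval excluding zero. A constant response
short-circuits to all-zero betas rather than a singular fit. Paired
track comparisons use the two-sided Wilcoxon signed-rank test (exact
method below 5 pairs).

## Synthetic sessions

The generator reproduces the statistical structure each stage assumes,
at the protocol's design point: two 200-cm tracks, 16 laps on track 1
versus few on track 2 in the first exposure, ~15-min re-exposures,
rest epochs of 30 min (PRE, POST2) and 60 min (POST1), 25-Hz tracking
with 0.1-cm noise, 1-kHz LFP. Defaults that the protocol does not fix
were chosen once as field-typical values: 50 place cells per track
(40% with fields on both tracks, drawn independently per track to
emulate global remapping, identical across exposures), 15-Hz in-field
peak rate with 15-cm Gaussian tuning, 30 cm/s mean running speed with
per-half-lap jitter, 12-s reward pauses, 8-Hz theta, 0.5-Hz rest
baseline against 0.05 Hz out-of-field during locomotion (pyramidal
cells are near-silent out-of-field while running — without this,
single-lap maps would be dominated by stray spikes), sleep replay
rates 0.03 and 0.02 events/s for tracks 1 and 2 (the magnitudes the
protocol is designed to measure), awake replay at 0.1 events/s of
immobility with a 15% remote fraction in re-exposures, 15× time
compression, and a 50/50 forward/reverse mix (awake-replay
directionality is deliberately a parameter, not an assertion).

Phase precession is a linear phase–position coupling referenced to the
LFP trough: a cell's preferred phase moves through 0.8·2π as the
animal crosses its field, so cells with fields behind the animal fire
early in the cycle and cells ahead fire late, producing decodable
theta sequences without further mechanism. Phase tuning is a
normalized squared raised cosine, concentrating spikes near the
preferred phase at fixed mean rate.

Replay bursts place each participating cell's spikes (Poisson, mean
1.5) at its field-crossing time along a constant-velocity virtual
trajectory, with 6-ms jitter; scheduled bursts last 150–350 ms,
involve ≥ 5 units by construction, never overlap, and lie inside the
true sleep intervals (sleep kind) or the wake blocks (rest kind, with
the position wander gated off around each rest event — awake replay
happens in stillness). Every burst also elevates ripple-band LFP power
and drives a multi-unit hash surge (80 Hz per multiunit group, sin²
envelope) that emulates the unsorted multi-unit activity real
recordings pool across channels; without it the MUA trace of ~100
sorted units is sparse enough to dip below baseline mid-event and
fragment detection. Rest epochs alternate 60-s-aligned wake/sleep
blocks (first 2 min awake, then 10-min sleep blocks separated by 1-min
wake), modulating baseline rate (×1.2 sleep, ×0.8 wake) and movement;
PRE carries structureless population bursts (random 15-cell subsets
plus ripple power) instead of sequence content. The LFP is pink noise
plus movement-gated theta, sleep-gated delta, and per-event ripple
bursts, distributed across three channels with distinct band gains so
spectral channel selection has a real choice to make; the pipeline
only consumes band power and phase, so no further spectral realism is
attempted.

All randomness flows through seeded generators with fixed sub-stream
offsets: a fixed config yields a byte-identical session.

### What the synthetic sessions do not show

Real recordings have drifting electrodes, bursty non-Poisson spiking,
overdispersed participation, sleep stages with genuinely different
spectra, variable compression within events, and replay content that
is not a constant-velocity sweep. Passing the recovery tests therefore
establishes that the implementation is correct and calibrated under
the model's assumptions — not that these thresholds are optimal for
any particular real dataset. The type-I calibration (structureless
events against the three-shuffle conjunction) is the part that
transfers most directly, since it does not depend on the embedded
signal model.

## Problem sizes used in the shipped checks

The test suite runs a reduced session (30 cells/track, 4+2 laps,
10-min rests) for unit-level checks, and the full-scale recovery check
uses seed 1 with 50 cells/track, 15-min re-exposures and a 30-min
POST1 embedding ~80 events, scored with the default 1000 shuffles.
Type-I calibration uses 500 structureless events × 1000 shuffles;
theta monotonicity compares 2/4/8-lap sessions at 100 shuffles per
cycle. The acceptance script simulates the full default protocol and
reports the median re-exposure decoding error (~3 cm against the
15-cm bound, ~2700 locomotion windows).

## Known limitations

- The LFP control's REM rule is implemented as printed despite its
  internal contradiction; it is a control only.
- Split rescue keeps the first significant half; an event with two
  independently significant halves counts once.
- The decoder assumes Poisson spiking and independence across units;
  no state-space smoothing across windows is applied (out of scope).
- `simulate_run_epoch` models constant-speed traversals with terminal
  pauses; mid-track stopping (and thus mid-track awake replay) is not
  generated.
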