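# Methods

This note documents the model behind `tagscope`, the numerical
conventions it commits to, what the virtual microscope does and does not
emulate, and the design choices made where more than one convention was
defensible.

## Event model and timing

Everything is built on integer picoseconds. All configured frequencies
are converted once, `T = round(1e12 / f)`, and every subsequent
computation — snake end times, gate arithmetic, phase anchoring — is
exact integer arithmetic. This removes float-comparison ties from
allocation: a photon exactly on a cell boundary has a well-defined home
(the next cell), and the same stream always reconstructs to the
byte-identical result.

A stream is a time-ordered sequence of `(channel, time_ps)` tags.
Channel roles are declared in the configuration: exactly one sync source
(line sync *or* frame sync, never both), at least one spectral channel,
optionally a TAG-lens sync and a laser reference channel, at most 18
inputs in total. A negative input number marks a falling-edge channel;
thresholds are carried as metadata only (discrimination is a hardware
step).

## Snake construction

For a frame starting at `t_f`, line `k` occupies
`[t_f + k·T_line, t_f + (k+1)·T_line)`. The visible window of duration
`ff·T_line` is centered in the line (`t0 = (1−ff)/2 · T_line`), and
column bin edges are `t0 + round(c · ff·T_line/cols)` — cumulative
rounding, so bins tile the window exactly and the total visible time per
line is `round(ff·T_line)` regardless of divisibility. Pixel bins are
uniform in *time*: no arcsine correction for the resonant mirror's
sinusoidal velocity is applied (edge discarding is the only distortion
handling; a spatial remap would be a post-export step and is out of
scope). Bidirectional scans reverse the column order of odd lines and
optionally shift their windows by `bidir_phase_ps` (the line-shift
correction).

The snake is rebuilt for every frame, anchored to the *measured* first
line sync of that frame, so slow scanner drift never accumulates.
Within a frame, lines sit at nominal spacing; missing line syncs (gap >
1.5 nominal periods) are bridged by inferred syncs and counted, so a
dropped tag costs bookkeeping, not a frame. Frame-sync-only wirings
buffer one frame of photons and divide each measured frame interval into
`rows` equal lines (nominal period for the trailing frame).

## Allocation

A photon at `t` belongs to the first cell whose end time *exceeds* `t`,
provided `t` lies in that cell's own interval; otherwise it is
discarded-early (leading margin or turnaround gap), after-frame, or
pre-sync (no usable reference yet). The lookup is
`searchsorted(end_times, t, side="right")` plus an interval check,
contract-identical to a linear scan (property-tested on randomized
snakes). Turnaround photons are discarded rather than snapped to the
nearest cell; the discard convention is explicit in the statistics so
the alternative could be quantified. Every spectral tag lands in exactly
one class, and the four class counters must sum to the spectral tag
count — asserted on every run, not just in tests.

## Axial (TAG lens) mapping

The lens phase is anchored to the most recent lens sync:
`φ = 2π·((t − t_sync) mod P)/P + φ0`, depth `z = (1 + sin φ)/2`, plane
`min(floor(z·planes), planes−1)`. Binning is uniform in z (not in
phase), so the arcsine dwell law — outer planes visited longest —
emerges naturally, and voxel skipping within a single volume follows
directly from the lens/scanner frequency mismatch. `φ0` is exposed in
the configuration because the phase of plane 0 relative to the sync
pulse is a hardware convention, not something the software can infer.
Photons arriving before the first lens sync have no phase reference and
are counted as pre-sync discards.

With the instrument's line rate (15.778 kHz, the bidirectional rate of
an 8 kHz resonant scanner) and a 189 kHz lens, a 64-column line gives a
pixel dwell of ~0.79 µs, ~0.15 lens periods: each pixel sees only a
phase arc per volume, so roughly 60% of voxels go unvisited in any
single 64×64×8 volume, while the incommensurate volume/lens periods
shift the arc every volume and ~40 volumes suffice to visit every
voxel. Note the volume rate scales inversely with the row count at a
fixed resonant line rate — 64-line volumes repeat at ~247/s, 512-line
volumes at ~31/s. The coverage analysis samples the trajectory at the
laser-pulse clock, the natural granularity of excitation.

## Demultiplexing

Gates are half-open: `Δ = (t − t_ref) mod T` with stream 0 on
`[0, T/2)` and stream 1 on `[T/2, T)`; a boundary photon joins the later
stream, mirroring the allocator's strict-exceeds rule. The declared gate
convention at exactly `Δ = T/2` is a choice, not a measurement. Two
streams are supported; the schema carries `n_streams` so a
generalization would not change stored artifacts.

Replayable recordings store only every Nth laser reference pulse
(default N = 1000, emulating the conditional filter's rate matching);
virtual pulses are extrapolated at the nominal period between
references, which is exact for a periodic train and has bounded error
(N × per-pulse drift) otherwise.

Crosstalk mechanics: with photons emitted exactly at pulse times,
deterministic gating is perfect for any beam-delay error smaller than a
quarter period — errors alone cannot produce crosstalk. Leakage requires
arrival-time spread; the simulator provides it as an optional
exponential emission delay (fluorescence lifetime). The crosstalk study
therefore runs with a 2.5 ns lifetime — a realistic fluorophore value —
where a 1 ns beam-delay error yields ~9% crosstalk and 2 ns ~12%,
strictly monotone; the purity check runs with zero lifetime and must
yield exactly zero.

## Accumulation and display

Counts are int64 throughout; a voxel's value is exactly its photon
count. (Spectral channel, demux stream) pairs are accumulated in
separate buffers and never blended. The rolling display window keeps the
integer sum of the last N frames (incrementally maintained, verifiable
on demand against a fresh sum); dividing by N is deferred to render
time so no precision is lost. The depth projection is the max over
planes of the per-plane sums across frames. An optional z-normalization
divides each plane by its analytic arcsine dwell weight before
projecting — this equalizes plane brightness without consulting the
data and is what the vessels-silhouette fidelity figure uses; raw
projections are the default. TIFF export saturates at 65535 with a
warning (16-bit pages).

## The virtual microscope

The simulator emits line/frame syncs at the configured rates (optional
Gaussian jitter), lens syncs at the lens period from a seeded random
origin within one period (the free-running phase), sparse laser
references, and photons drawn per pulse per spectral channel as
Bernoulli trials with probability `brightness · P_pulse · I(row, col,
plane)`, `P_pulse ≤ 0.1`. Scan position is uniform in time across the
active window — deliberately matching the snake's binning — and
excitation is blanked during turnaround and before the first lens sync,
so every emitted photon has a well-defined true voxel. Sync tags sort
before photon tags at equal timestamps.

What this emulates: event rates and interleaving, frame/line/lens
timing relationships, per-pulse photon statistics, beam-delay errors,
emission-lifetime gate leakage, sync jitter and dropped-sync recovery.
What it does not: optical point-spread functions, detector afterpulsing
and dead time, discriminator threshold effects, analog-integration
comparisons, and sinusoidal mirror velocity (image-space distortion).
Passing round trips therefore certify the *event-processing* chain —
that the allocator inverts a faithful event stream exactly — not
optical image quality on real tissue.

Default study sizes (chosen to exercise the mechanisms at desk scale):
64×64 pixels, 8 planes where volumetric, 10–30 frames, brightness 0.5
(mean excitation probability ~0.05 per pulse on bright voxels), 80 MHz
laser, 15.778 kHz lines, 189 kHz lens. The 20-frame noise-free round
trip processes ~10⁵ photons.

## Known limitations

- Live hardware acquisition and the vendor's proprietary stream format
  are out of scope; the open dialect plus the simulator cover the
  computational contract, and a converter would plug in at
  `stream_io.read_tag_stream`.
- Exactness is defined against the ledger at zero jitter/lifetime;
  jittered syncs shift whole frames (the per-frame rebuild tracks the
  measured sync), degrading per-voxel exactness gracefully rather than
  failing.
- `plane` assignment uses the photon's arrival time; with a nonzero
  emission lifetime the lens moves slightly between excitation and
  detection, which is physical and appears as a small exactness loss in
  lifetime studies.
- The frame-sync-only path buffers one frame of photons in memory;
  line-sync wirings stream with bounded per-frame buffers.
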