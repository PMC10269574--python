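# Methods

## Paradigm model

The session timeline is encoded explicitly: a 40-s device baseline
(5-s count, 15 s eyes open, 5-s countdown, 15 s eyes closed) followed by
a 240-s task of alternating blocks — stimulus first — each holding four
5-s sentence events, giving 24 stimulus and 24 control sentences.  The
builder accepts any (sentence duration, sentences per block, task
duration) triple whose task duration is an exact multiple of one
stimulus+control cycle, and rejects anything else naming the residual
seconds.  Event times are exact rationals (`fractions.Fraction` of
seconds), so block boundaries are exact at any sampling rate and window
labelling never suffers float drift.  The 5-s on-screen time is taken as
gapless (4 × 5 s = 20 s per block); the baseline is part of the schedule
but excluded from analysis, with the device marker defining task time
zero.

Analysis windows are labelled against the schedule with a half-open
interval convention: a window fully inside one event inherits its kind,
a window ending before the first task event is `pre_task`, and a window
spanning a boundary is `mixed`.  With 5-s windows aligned to task onset
no `mixed` windows occur in the published design; they matter only for
non-default window lengths and are kept (label-filtering is a downstream
configuration choice).

## Ingest

Raw CSVs are read through an explicit dialect: a column-name map, an
affine raw→µV conversion `uv = (raw − offset) × scale` (headset exports
are unsigned integers around a mid-rail), the marker column name and the
delimiter.  The default dialect is the identity conversion with a
`MARKER` column, which is also what the synthetic generator writes, so
fixtures round-trip bit-for-bit modulo the 6-decimal float format.  Sample
indices are 0-based, intervals half-open, and the 10–20 parity rule
(odd-numbered labels left, even right) is enforced on any montage.  The
task onset is the first occurrence of marker "1"; extra occurrences win a
logged warning, a missing marker is an error that points at the manual
override.  Recordings shorter than onset + 240 s are truncated with a
warning rather than rejected — a pragmatic choice for real sessions that
stop early.

## Preprocessing

Defaults: zero-phase band-pass 1–45 Hz.  The pass band spans all analyzed
bands (the highest ends at 45 Hz) while removing drift below 1 Hz and
mains energy above.  The default realization is a 6th-order Butterworth
applied forward–backward (`sosfiltfilt`).  Order 6 rather than a lower
order is deliberate: forward–backward filtering squares the magnitude
response, and at order 4 the 35 Hz Gamma component already loses ≈2% of
its power, which visibly biases normalized profiles; at order 6 the
passband is flat to <0.3% at 35 Hz.  An FIR path (`firwin` + `filtfilt`)
with configurable tap count is selectable through the same `FilterSpec`.

Windows are consecutive, non-overlapping, 5 s long (one sentence);
trailing samples that do not fill a window are dropped (only truncated
recordings are affected — 240 s divides evenly).  Each window carries its
RMS in µV.

Artifact rejection replaces visual inspection with a deterministic
two-rule criterion: a window is flagged if its RMS exceeds the channel's
median + k×MAD (k = 5) across windows, or if any sample exceeds ±150 µV
after channel DC removal.  Both thresholds are configuration; the rule is
idempotent and monotone (tightening a threshold never unflags).  A
channel with zero RMS dispersion (MAD = 0) falls back to the amplitude
rule alone.  With the defaults, planted bursts ≥300 µV are always caught
while clean-window false flags stay well under 5% — the margins the
acceptance script measures.  The k = 5 / 150 µV defaults are conventional
robust-outlier choices for frontal EEG, set once and surfaced in config.

## Spectral estimation

Each window gets a raw periodogram: `rfft`, squared magnitude, one-sided
scaling such that the bin sum equals the window's mean-square value.
This makes Parseval's identity the cross-check between the RMS machinery
and the spectral path, and it holds to float precision on every window.
No taper is applied by default (band powers of interest sit on exact
bins for the synthetic tones; for real data a power-normalized Hann taper
is config-gated).  Band powers are sums of bins over half-open ranges
[low, high); the half-open rule makes the five analyzed bands an exact
partition of [4, 45) Hz and resolves shared edges (a 12 Hz tone belongs
to BetaL, not Alpha) — a convention of this package, stated once.

Per electrode, the "average of each wave" is the arithmetic mean of
per-window band powers in the power domain (µV²), over accepted windows
(artifact-free, stimulus + control labels by default; a stimulus-only
switch exists).  Normalization divides by the electrode's sum over the
five analyzed bands, so each electrode's profile lies on a simplex;
Delta is computed and exported in raw form but excluded from the
normalized display.

## Asymmetry statistic

The per-band statistic is the percentage-point difference of normalized
band power, right minus left, with each side's value the unweighted mean
of its two electrodes.  This choice makes the signed bars, the simplex
normalization and the ±100 bound mutually consistent; it also forces the
five band differences to sum to zero, so a participant cannot be
left-dominant in strictly all bands under this normalization — a useful
sanity property to keep in mind when comparing with per-figure
descriptions of real cohorts.  The classical ratio index
100×(R−L)/(R+L) is available for sensitivity analysis.  Dominance per
band uses a ±0.5 pp tie zone (conservative; real data rarely land inside
it).  Cohort aggregation is the unweighted mean over participants — not
weighted by accepted-window count — matching the equal-subject reading
of a group average; per-band dominance counts and the number of
participants with any right-dominant band are reported alongside.

## Synthetic data

The generator emulates the acquisition: full 14-channel headset montage,
128 Hz (256 Hz available), mid-rail DC offset (4200 µV), the complete
baseline+task timeline, a marker "1" at the boundary sample, Gaussian
broadband noise and optional artifact bursts (1-s Hann-enveloped 25 Hz
transients centred in a chosen task window).  Each band contributes one
representative tone (Delta 2, Theta 6, Alpha 10, BetaL 14, BetaH 20,
Gamma 35 Hz — strictly interior to the half-open bands, and exact DFT
bins for 5-s windows at 128 Hz), with per-channel random phases.  A tone
of amplitude A carries power A²/2, so the normalized profile is
closed-form and serves as ground truth.

Defaults chosen once as realistic study conditions: total analyzed-band
power 400 µV² per hemisphere (≈12.6 µV per-band amplitudes, i.e. ~20 µV
channel RMS), noise SD 5 µV.  Broadband noise adds equal power to both
hemispheres' bands and therefore compresses normalized differences
toward zero by a factor ≈ P/(P+N); at these levels a planted 14 pp
difference is recovered at ≈13.5 pp, inside the ±2 pp recovery band the
tests assert.  Cohort planting solves band amplitudes from a requested
per-band difference vector; since both hemisphere profiles must sum to
one, the differences must cancel across bands — bands not named in a
plan absorb the balancing remainder equally, and a fully specified plan
with nonzero sum is rejected.

What the generator does *not* emulate: 1/f background spectra, alpha
blocking, evoked responses, inter-channel coherence structure, or any
aphasic pathology.  Passing recovery tests therefore demonstrates that
the pipeline's bookkeeping and statistics are correct, not that the
analysis is robust to physiological EEG in all its variety.

## Problem sizes and numerics

Tests and the acceptance script use the published problem sizes — 48
five-second windows per participant at 128 Hz, 9-participant cohorts —
with 20-seed replications for the null-bias and artifact-rate bounds;
null-cohort replications generate only the four analysis electrodes,
since the remaining channels never enter the statistic.  Spectral
agreement with a brute-force O(n²) DFT oracle is asserted at 1e-8
relative, Parseval at 1e-6 relative, zero-noise analytic recovery at
1e-3 absolute (the residual is the filter's <0.3% passband shaping),
and planted-asymmetry recovery at ±2 pp.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; fixture CSVs
are written with a fixed 6-decimal format so identical specs produce
byte-identical files.

## Known limitations

- The artifact criterion is a reproducible surrogate, not a clone of
  expert visual inspection; its thresholds were not tuned to any real
  recording.
- Group results on real cohorts depend on the unstated unit scaling of a
  given headset export; the dialect mechanism absorbs this but cannot
  guess it.
- No statistical inference is performed on the asymmetries (by design);
  the package reports descriptive statistics only.
- EDF/BDF and proprietary binary formats, re-referencing schemes, ICA
  and time-frequency analysis are out of scope.
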