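# Methods

`sociolfp` analyzes trial-epoched local field potentials (LFP) from a
social nonmatch-to-goal task: a monkey alternates between performing
trials (Actor) and watching a human partner perform them (Observer), and
the partner is either a Good Agent (GA1/GA2, always correct) or a Bad
Agent (BA, always incorrect). The pipeline filters visually selective
channels, computes baseline-relative multitaper spectrograms, contrasts
conditions with per-bin permutation tests under FDR control, extracts
band dynamics and latencies, and decodes the previous trial's correct
target from pre-target beta power. Because no public recordings exist
for this task, a synthetic-session generator with planted, quantitatively
known effects serves as the verification substrate for every stage.

## Data model and timing conventions

A session stores a `trials x channels x samples` array epoched on target
onset (time 0), window (-0.8, 3.0) s, with half-open sample bins
[t, t + 1/fs). The sampling rate is a stored attribute, 1000 Hz by
default — ample for the 100 Hz analysis ceiling. Movement- and
feedback-aligned views are sliced from the stored epoch using per-trial
event times (`realign`), so one stored alignment serves all three
analyses. Response time is `t_touch - t_go` (reaction + movement).

Each trial also records the interaction context (`context_agent_type`):
for observer trials this is the partner's type; actor trials inherit the
type of the surrounding interaction so Good-vs-Bad contrasts can be
formed within the Actor role as well.

On disk: HDF5 (`/lfp` float32, `/time`, scalar attributes) plus a
sibling `<name>.trials.csv`. Event times are written with `%.17g` and
read with round-trip float parsing, so write-read is bit-exact.

## Channel selectivity filter

A channel is *visually selective* if the trial-averaged voltage (ERP)
deviates from the pre-target baseline mean by more than 2 baseline SDs
for one contiguous run of >= 50 ms inside the 50-350 ms post-target
window. Choices where the criterion's description is ambiguous:

- two-sided (|v - mean|), matching the "+/- 2SD" threshold band;
- SD computed on the trial-averaged ERP, not single trials;
- one *contiguous* run of 50 ms (not cumulative);
- baseline window defaults to (-0.3, 0) s; the (-0.2, 0) variant used
  for display elsewhere is a parameter.

Channels failing in both roles are excluded downstream; actor trials are
restricted to correct ones, observer trials all included (BA trials are
errors by design).

## Multitaper spectrograms

300 ms windows stepped every 10 ms; K = 2 unit-norm DPSS tapers at
half-bandwidth W = 5 Hz (NW = T*W = 1.5, and 2NW - 1 = 2 — reading the
stated "frequency bandwidth" as the half-bandwidth is the only reading
consistent with 2 tapers). Each window is mean/trend-removed, tapered,
and FFT'd with zero-padding to `ceil(fs / 1.5)` points, giving ~1.5 Hz
spacing (the grid is reported from the actual spacing, fs/NFFT); the
grid is truncated at 100 Hz. Taper periodograms are averaged unweighted
(eigenvalue weighting is an option; at these concentrations, lambda =
0.999/0.969, it is immaterial) and scaled to one-sided PSD. Times are
window centers; the first window starts at epoch start. A 50 Hz notch
is available for line-contaminated data and off by default.

Relative spectrograms are 10*log10(P/B), with B the per-frequency mean
power of the single window fully inside the 300 ms pre-target baseline,
averaged over trials. Two reductions exist deliberately:

- `per-trial`: each trial's dB map. This is the input to per-bin
  permutation tests and decoding features. Per-trial dB carries the
  chi-square log bias (E[log P] < log E[P], about -1.2 dB at 4 degrees
  of freedom), which is common to all conditions and cancels in every
  contrast.
- `mean`: dB of the trial-mean power — the unbiased display and
  time-course convention (a stationary session reads ~0 dB).

**Baseline pooling.** When two trial groups are contrasted, both are
normalized by one baseline computed from the union of their trials. A
per-group baseline injects a group-common offset (baseline sampling
noise) that trial permutations cannot exchange away; we measured a ~4x
inflation of the per-bin false-positive rate with per-group baselines.

Bands: alpha 7-14 Hz (7-15 variant available), beta 20-30 Hz, gamma
45-100 Hz, "low" 7-20 Hz; band time courses are unweighted means over
the grid frequencies inside the band, inclusive.

## Permutation statistics and FDR

Per-bin two-sided permutation test on the difference of group means,
p = (1 + #{|d*| >= |d|}) / (N + 1) (add-one avoids zero p-values),
N = 5000 by default. One relabeling per permutation is shared across all
bins, preserving the spatial correlation of the null; independent
per-bin shuffling is an option. The exchangeable unit is the trial
(channel-averaged maps): stacking channel x trial copies makes units
dependent through shared trial events and miscalibrates the null.

FDR step-up: order p ascending, find the largest k with
p(k) <= alpha*k/m, reject all p <= p(k), alpha = 0.01. This printed rule
is the Benjamini-Hochberg form; `method="by"` divides alpha by the
harmonic sum (Benjamini-Yekutieli). Note the discreteness interaction:
the smallest attainable p is 1/(N+1), so rejections require at least
m / (alpha*(N+1)) bins at the floor — map analyses must size N against
the grid (the scaled analyses below use N = 2000 on restricted grids,
sized from this arithmetic).

Kruskal-Wallis (midrank ties, chi-square p) is used for behavioral and
latency comparisons; the all-values-identical degenerate case returns
H = 0, p = 1.

## Band dynamics

Extremum latencies are the windowed global extremum (beta: minimum,
gamma: maximum) within [0, 0.6] s after target onset and within the
movement-locked window (-median RT, median movement-to-touch); ties
break to the earliest time. The unit of observation for latency
statistics defaults to the channel and is recorded in the output. The
beta-gamma response pattern is the point-wise gamma - beta difference;
pattern similarity is Pearson r (invariant to positive affine maps).
The movement-locked alpha contrast compares per-trial mean alpha power
in (-0.3, 0) vs (0, 0.3) s around each trial's movement onset.

## RegOLE decoding

Features: channel-wise beta-band relative power at 50 ms-spaced analysis
bins from -200 to +50 ms around target onset. Targets: the previous
trial's correct (x, y) position, sign-coded in {-1, +1}^2. The decoder
is two independent ridge regressions (one per axis) minimizing
||W R + b - C||^2 + lambda ||W||^2 in closed form with centered features
and targets (the printed objective places b inside the product; as a
free intercept the two forms are equivalent reparameterizations).
lambda = 1.0 on per-fold z-scored features by default.

Accuracy: 1000 resampling runs by default (tests and the acceptance
script use 100, stated sizes below); each run draws 8 trials per
location (32 total), and each leave-one-trial-out fold removes one
random trial from each of the other three locations, leaving 28 training
trials, 7 per location. Joint accuracy (both axes correct, chance 1/4)
is primary; per-axis accuracies are reported too since "proportion
correctly classified" is ambiguous. sign(0) maps to +1.

Significance: label permutations re-scored by the same procedure at a
reduced run count (`n_runs_null`, default 100); a bin is significant iff
the real accuracy reaches the (1 - tail) null quantile, tail = 0.001
(the 0.1% upper tail). Under shuffled labels, accuracy variance is
dominated by between-shuffle spurious decodability, not within-shuffle
run noise; chance-level estimates therefore average many shuffles with
few runs each.

## Synthetic sessions

The generator emulates the study's condition structure: cells
(actor, SELF), (observer, GA1/GA2/BA), agents with always-correct /
always-incorrect outcomes, nonmatch-consistent targets, and lognormal
response times (medians: monkey 0.50 s; GA1 0.95 s, GA2 0.80 s, BA
1.10 s, sigma 0.12 — preserving the reported orderings: GA2 faster than
GA1, BA slower than GA, at roughly the reported magnitudes). Trials are
interleaved round-robin to mimic agent alternation. The touch-to-
feedback delay is 0.5 s (shorter than the task's holding periods) so
feedback falls inside the stored epoch even for slow BA-like RTs; RTs
whose feedback would still fall outside are resampled with a warning.

Signals: per-channel 1/f pink background (unit variance scaled to
noise_sd = 20 uV). Planted effects multiply the band-passed component of
that background by a Gaussian-envelope power gain anchored to a task
event — so a +3 dB planted gain is by construction a +3 dB expected
deviation in the relative spectrogram, and ground-truth masks are exact.
Expected-dB maps convolve the envelope with the 300 ms analysis window
in time and the +/-5 Hz taper concentration band in frequency, so
leakage bins are part of the prediction rather than slack. The default
repertoire mirrors the reported phenomenology qualitatively:
actor-early / observer-late gamma bursts with anti-phase beta dips,
opposite alpha modulations after movement, and observer-BA low-frequency
(7-15 Hz) boosts after the partner's movement and after feedback. Gains
(+/-1.5 to 3 dB) are chosen for testability; the source maps are
color-coded and publish no dB effect sizes.

The evoked potential on selective channels is a damped sinusoid, 4 Hz
with 0.35 s decay, amplitude `evoked_amp_sd_units` x the baseline ERP SD
(noise_sd / sqrt(n_trials), since the selectivity criterion thresholds
the trial-averaged ERP). The frequency choice is geometric, not
cosmetic: the criterion demands 50 contiguous ms beyond 2 SD, and a
faster carrier's half-cycle above threshold is shorter than 50 ms, so
at 8 Hz the criterion cannot fire regardless of amplitude.

Pre-target beta tuning: each channel's beta power is scaled by
`tuning_gain_db @ (x, y)` of the previous correct target (default
matrix: +/-2 dB sign patterns covering both axes), with an envelope that
is full until 0.1 s after target onset and rolls off to zero by 0.3 s —
decodable at the pre-target bins, absent late in the trial.

Reproducibility: one master seed; trial k's stream derives from
(seed, k), so any trial regenerates in isolation.

### What the generator does not emulate

No biophysical forward model, spike-field structure, cross-frequency
phase coupling, line noise, artifacts, eye movements, or session-level
heterogeneity (a generated session is one homogeneous pseudo-session;
between-session variance of the real study is out of reach). Passing
tests therefore demonstrate that the *pipeline* recovers known structure
under realistic 1/f noise and task timing — not that the biological
claims would replicate.

## Problem sizes in tests and the acceptance script

Chosen so the full suite and script each run in minutes: permutation
calibration, 500 null pairs x 500 permutations; FDR null maps, 200
replicates of 20x20 grids (15 trials/group, N = 500); map recovery, 100
trials/group, 4 channels, grid limited to <= 45 Hz with N = 2000;
decoding, 80 trials, 8 channels, 100 runs, 100 permutations x 10 null
runs, tail 0.01; selectivity, 50 planted + 50 null sessions; dynamics,
40 channels x 60 trials. Full-fidelity settings (N = 5000, 1000 runs,
1000 permutations, tail 0.001) remain the library defaults.

## Known limitations

- The permutation/FDR machinery tests mean differences of per-trial dB
  values; heavy-tailed power distributions are handled by the log
  transform, but no cluster-level inference is provided.
- With few permutations relative to the grid size the FDR step-up can
  reject nothing even for real effects (discreteness, above).
- `movement_window` uses per-condition median RTs on trial-averaged
  time courses; per-trial alignment is available via `realign` but the
  default reproduces the condition-level convention.
- The decoder assumes four balanced target locations; other layouts
  require changing the resampling scheme.
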