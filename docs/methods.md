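# Methods

This note documents the model and the numerical choices behind `ecogwarp`:
what is computed, which conventions were fixed where several were
defensible, what the synthetic generator does and does not emulate, and the
known limitations.

## Epoching and kinematics

Hand position is a time-stamped 3-D trace (nominal 40 Hz, cm; X orthogonal
to the chest, the dominant axis of a reach). Velocity is obtained by
central differences (`numpy.gradient`, one-sided at the ends, tolerant of
slightly irregular stamps) followed by a centered moving average of
5 samples (125 ms) per component; speed is the Euclidean norm of the
smoothed vector. The smoothing length is a robustness choice for tracker
jitter at 40 Hz — it can be set to 1 to disable, which is also what the
noiseless round-trip tests use, since unsmoothed central differences
bracket the true threshold crossing to within one sample.

Movement onset is the first sample whose speed exceeds **0.5 cm/s**,
searched from the auditory cue onward when cue times exist (pre-cue
twitches cannot trigger). That instant is t = 0; every trial is cut to the
half-open window **[−4 s, +8 s)**, so epoch lengths are determined by the
window and the sampling rates alone (14 400 samples at 1200 Hz, 480
kinematic samples at 40 Hz). Onset thresholding uses the 3-D speed by
default; DTW later uses the signed X velocity (see below).

## Spectrograms and ERD/ERS normalization

Short-time Fourier power with a **100 ms Hamming window** advanced in
**10 ms hops**. Each segment is zero-padded to one second of samples so
frequency bins land on an exact 1 Hz grid; this is spectral interpolation —
the intrinsic resolution remains that of the 100 ms window. Only windows
fully inside the epoch are used and each frame is stamped at its window
center (a 12 s epoch yields 1191 frames at −3.95 … +7.95 s). Power is
`|FFT|²` with no window-gain compensation: every downstream comparison is a
ratio to baseline, in which the gain cancels.

Event-related changes are percent change per frequency relative to the mean
power over **−2 … −1 s** before onset, computed per trial (a pooled
session-level baseline is not the default; per-trial baselines absorb slow
impedance drifts). The normalization stores B(f) and is invertible. A zero
baseline at any frequency is an error, not a silent NaN.

The pipeline analyses the 0–200 Hz portion of the grid (fmax
configuration), which covers the beta (12–30 Hz), gamma (65–140 Hz) and
gamma-warp (65–90 Hz) bands with headroom; `compute_spectrogram` itself
defaults to the full 0–600 Hz axis.

## Dynamic time warping

Local cost is the absolute difference of velocities (1-D Euclidean).  The
recursion is the symmetric step pattern with no slope constraint —
steps {(1,0), (0,1), (1,1)} weighted (1, 2, 1), `g(0,0) = 2·d(0,0)` — and
`normalized_cost = total / (N + M)`.  Backtracking breaks ties preferring
the diagonal step, then the reference-advancing step; this matters on
near-zero-velocity pauses, where many cells tie, and fixes the result
deterministically.  No global band or window constraint is applied.

Warping runs on the full-epoch **signed X velocity** resampled (linear
interpolation) onto the spectrogram frame grid; a speed-magnitude option
exists (`warp_on="speed"`). Signed velocity distinguishes reach from
retrieval, which speed cannot.

Applying a path maps each reference frame to the arithmetic mean of the
query frames paired with it (segmented means; the path's monotonicity and
continuity make this well defined). Spectrograms are warped column-wise —
the frequency axis is untouched. A sample-level time-domain warp
(`warp_signal_time_domain`) is provided only to demonstrate why that is the
wrong operation: stretching the waveform shifts instantaneous frequency and
smears harmonic content such as line noise.

`path_from_gamma` derives registration paths from 65–90 Hz band power
instead of kinematics, for settings (e.g. imagined movement) where no
kinematic trace exists; it is noisier than kinematic warping.

## Ensemble statistics

* **Reference selection** — default is the *medoid* trial (minimum summed
  normalized DTW cost to all others); a fixed index is available. The
  permutation evaluation uses every trial as reference in turn.
* **Permutation evaluation** — all ordered (reference, query) pairs; RMS is
  the root of the cell-count-normalized mean square, so values are
  comparable across grid sizes. Log errors enter a one-sided Welch
  (unequal-variance) t-test, warped < unwarped; the unwarped errors are the
  null. The test is unpaired by default (two error distributions); a
  paired variant on the same pair structure is available by flag. Pairs
  with zero error (log undefined) are excluded and reported, and an
  all-zero session raises. One test per session; no multiple-testing
  correction is applied or needed.
* **Band-change test** — per-trial mean normalized band value in a movement
  window (default 0–1 s) vs the baseline window, compared across trials
  with a two-sample Kolmogorov–Smirnov test; the sign of the mean
  difference is the reported ERD/ERS direction.
* **Kinematic warp-error report** — RMS residual between reference and
  warped query velocities for every pair; a large session median (e.g.
  under frequent target overshoot, which inserts a corrective reversal
  other trials lack) flags sessions where kinematic warping is unreliable.
* **Rectified EMG** — onset-aligned sample-wise mean of |EMG|, or
  frame-wise rectified amplitudes warped along the same registration paths
  as the spectrograms, preserving the sharp activity fall at movement end
  that onset alignment washes out.

## Synthetic sessions

The generator stands in for patient recordings that cannot be shipped. Per
trial (15 s recording, movement nominally 5 s in, cue 0.5 s earlier):

* **Kinematics** — minimum-jerk (quintic) segments: reach of 40 cm, pause,
  retrieval; durations drawn from normal distributions truncated at
  mean ± 3 sd (symmetric truncation keeps the mean unbiased; parameters
  whose mean − 3 sd ≤ 0 are rejected at validation). Defaults: reach
  1.2 ± 0.3 s, pause 1.3 ± 0.4 s, retrieval 1.0 ± 0.3 s, onset jitter sd
  0.3 s. Optional overshoot (probability per trial) reaches 15 % past the
  target and appends a 0.35 s corrective return. Small fixed Y/Z
  components (8 %/5 % of X) make the trace genuinely 3-D. Positions are
  noiseless: the electromagnetic tracker's error is negligible against the
  40 cm movement, and onset/boundary bookkeeping is exact by construction.
* **Ground truth** — `true_onset` and the phase boundaries are where the
  *analytic* speed crosses 0.5 cm/s (evaluated on a 1 ms grid), i.e. what
  an ideal threshold detector would report; the drawn durations are kept
  separately for distributional checks. Each trial carries its expected
  normalized spectrogram (template) built from the same spectral model the
  signal is sampled from, with the envelope and speed time courses smeared
  by the squared analysis window. Band-edge spectral leakage is *not*
  modeled; it biases measured and template spectrograms alike, which is
  irrelevant to the conventional-vs-warped comparison.
* **ECoG** — spectral synthesis: 1/f background (flat below 1 Hz); a
  beta-band noise oscillation at 4× the background level whose envelope is
  multiplied by `erd_depth` (default 0.5, i.e. power falls to 25 %) while
  speed exceeds the onset threshold (gate smoothed by a 100 ms Hann
  window); gamma-band noise whose power is `ers_gain` (default 0.1 per
  cm/s) times speed, relative to the background level at the gamma band
  center; optionally a mains sinusoid (off by default; 60 Hz is the
  conventional choice when enabled, at twice the background's standard
  deviation).
* **EMG** — white noise with amplitude `sqrt(floor² + (gain·speed)²)`
  (floor 1 a.u., gain 2 a.u. per cm/s): silent at rest, burst proportional
  to speed.
* **Determinism** — every trial draws from
  `SeedSequence([session_seed, trial_index])` spawned into independent
  kinematics/ECoG/EMG streams; identical parameters give bit-identical
  sessions.

What the generator does **not** emulate: cross-frequency coupling, trial-
to-trial amplitude variability of the neural response itself, artifacts
(eye movement, muscle contamination of ECoG), non-stationary noise floors,
or any biophysical cortical model. Passing tests therefore demonstrate that
the alignment machinery behaves as designed under movement-timing
variability — not that it is robust to every property of real recordings.

## Numerical choices and edge cases

* DTW forward pass: an O(N) row recursion in numpy (the within-row
  horizontal chain is resolved with a running minimum over cumulative
  costs); compiled `numba` kernels are used when available and are checked
  against the numpy path in the tests. Backtracking matches predecessor
  sums with relative tolerance 1e−9 to absorb float associativity.
* Degenerate inputs raise: empty or non-finite series, fewer than 3
  kinematic samples, epochs that exceed the recording, zero baselines,
  empty bands, < 2 (or < 3) trials where the statistic needs more.
* Intervals are half-open [start, end); frame timestamps are window
  centers; band edges are inclusive.
* EDF recordings are read through `mne` when installed; the writer format
  is delimited text (plus JSON sidecars for ground truth, paths, reports).
  Reports are serialized with sorted keys so identical runs are
  byte-identical.

## Problem sizes

The test suite exercises the template-recovery and calibration experiments
at 20 sessions × 50 trials. `scripts/acceptance.py` uses 10 sessions × 40
trials for template recovery, 10 null + 2 jittered sessions for the
permutation evaluation, 1000 random pairs for the DTW oracle and 20 trials
for the onset round trip; these sizes give stable statistics while keeping
a full run to a few minutes on one CPU.

## Limitations

* The warp assumes a monotone, continuous correspondence between trials'
  time axes; movements with qualitatively different phase structure (extra
  sub-movements, omitted pauses) violate it and surface as large kinematic
  warp errors rather than as wrong-looking averages.
* Whether the original threshold convention applied to 3-D speed or X-only
  speed is a genuine ambiguity; 3-D speed is the default here with X-only
  behaviour recoverable from the signed-velocity series.
* Many-to-one frame aggregation by the mean slightly smooths the query
  spectrogram wherever the path compresses time; alternatives (median,
  resampling) were not implemented.
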