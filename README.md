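# ecogwarp

Kinematics-guided time-warped averaging of trial-based electrocorticographic
(ECoG) spectrograms.

## The problem

Averaging many repeated trials is the standard way to pull movement-related
components — beta-band (12–30 Hz) event-related desynchronization (ERD) and
gamma-band (65–140 Hz) synchronization (ERS) — out of noisy cortical
recordings. Averaging assumes the neural events occur at the same times in
every trial. For unconstrained reaching movements they do not: initiation
time, movement duration and speed all vary from trial to trial, so
onset-aligned ("conventional") averages smear and fragment the
movement-locked components.

`ecogwarp` aligns trials by their *arm kinematics* instead. Because band
power in motor cortex tracks arm velocity approximately linearly, warping
every trial's time axis so that its velocity profile matches a reference
trial also aligns the neural activity. The warp is found by dynamic time
warping (DTW) of the velocity profiles and applied to the per-trial
*spectrograms* — never to the raw signal, whose spectral content a time warp
would distort.

## Method

For each trial, epoched on [−4 s, +8 s) around the instant arm speed first
exceeds 0.5 cm/s:

1. **Spectrogram** — 100 ms Hamming windows, 10 ms hop, zero-padded to a
   1 Hz bin grid; power `P(f, t) = |STFT|²`.
2. **ERD/ERS normalization** — percent change per frequency,
   `V(f, t) = 100 · (P(f, t) − B(f)) / B(f)`, with baseline `B(f)` the mean
   power over −2…−1 s before movement onset.
3. **Registration path** — DTW between reference and trial X-velocity with
   local cost `d(i, j) = |v_ref(i) − v_q(j)|` and the symmetric step
   pattern, no slope constraint:
   `g(i,j) = min(g(i−1,j) + d, g(i−1,j−1) + 2d, g(i,j−1) + d)`,
   `g(0,0) = 2·d(0,0)`.
4. **Time-warped average** — each trial's normalized spectrogram is
   re-mapped frame-wise along its path (frequency axis untouched), then all
   trials are averaged cell-wise.
5. **Evaluation** — the reference is permuted across all trials; for every
   ordered (reference, query) pair the RMS difference over all
   time–frequency cells is computed warped and unwarped. The unwarped
   errors form the null; a one-sided Welch t-test on the log errors
   quantifies the variance reduction due to warping.

Since real patient recordings of this kind are not publicly available, the
package ships a seeded synthetic session generator (`ecogwarp.synthetic`)
that emulates the task: minimum-jerk reach/pause/retrieve kinematics with
realistic duration variability (reach 1.2 ± 0.3 s, pause 1.3 ± 0.4 s,
retrieval 1.0 ± 0.3 s, 40 cm reaches), 1/f ECoG background with beta ERD
and speed-locked gamma ERS, and speed-gated EMG bursts — with the analytic
ground truth (onsets, phase boundaries, expected normalized spectrogram)
attached to every trial.

## Worked example

```python
from ecogwarp import SessionParams, generate_session, run_pipeline

session = generate_session(SessionParams(n_trials=12, seed=101))
result = run_pipeline(session)
report = result["report"]

ev = report["permutation_evaluation"]
ks = report["band_change_ks"]
print(f"trials analysed      : {report['n_trials']}")
print(f"reference trial      : {report['reference']} (medoid)")
print(f"beta  12-30 Hz change: direction {ks['beta']['direction']:+d}, "
      f"KS p = {ks['beta']['p_value']:.2e}")
print(f"gamma 65-140 Hz change: direction {ks['gamma']['direction']:+d}, "
      f"KS p = {ks['gamma']['p_value']:.2e}")
print(f"warping benefit      : t = {ev['t_statistic']:.2f}, "
      f"p = {ev['p_value']:.2e} over {ev['n_pairs']} permutation pairs")
print(f"kinematic warp error : median {report['kinematic_warp_error']['median']:.2f} cm/s")
```

prints:

```
trials analysed      : 12
reference trial      : 6 (medoid)
beta  12-30 Hz change: direction -1, KS p = 7.40e-07
gamma 65-140 Hz change: direction +1, KS p = 7.40e-07
warping benefit      : t = -6.30, p = 6.29e-10 over 132 permutation pairs
kinematic warp error : median 2.47 cm/s
```

Reading: across trials, beta power drops during movement (ERD, direction
−1) and gamma power rises (ERS, +1), both significant by a two-sample
Kolmogorov–Smirnov test between movement and baseline windows. Warping the
spectrograms along the kinematic registration paths reduces their
trial-to-trial RMS variability (one-sided Welch t on log errors,
p ≈ 6 × 10⁻¹⁰ over all 12 × 11 reference permutations). The kinematic warp
error is the residual RMS velocity mismatch after warping — sessions where
it is large (e.g. frequent target overshoots) are ones where kinematic
alignment is unreliable.

The same pipeline is scriptable from the shell:

```sh
ecogwarp simulate --out session/ --trials 50 --seed 7
ecogwarp evaluate --session session/ --out report.json
ecogwarp average  --session session/ --method warped --out warped.npz
ecogwarp render   --spectrogram warped.npz --out warped.png
```

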