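import numpy as np
import pytest

from ecogwarp import (
    NormalizedSpectrogram,
    SessionParams,
    average_rectified_emg,
    band_change_ks_test,
    conventional_average,
    dtw_path,
    generate_session,
    kinematic_warp_error_report,
    permutation_evaluation,
    process_session,
    rms_error,
    select_reference,
    warped_average,
)
from ecogwarp.synthetic import NOMINAL_ONSET_S


def make_norm(values, hop=0.01):
    values = np.asarray(values, dtype=float)
    return NormalizedSpectrogram(
        np.arange(values.shape[0]) * hop, np.arange(values.shape[1], dtype=float), values
    )


def bump(ft, center, width=0.2, amp=30.0):
    return amp * np.exp(-0.5 * ((ft - center) / width) ** 2)


class TestSelectReference:
    def test_identical_trials_tie_at_zero_cost(self):
        v = np.sin(np.arange(60) / 10.0)
        assert select_reference([v, v.copy()], "medoid") in (0, 1)

    def test_outlier_is_not_the_medoid(self, rng):
        base = np.sin(np.arange(60) / 10.0)
        trials = [base + 0.01 * rng.standard_normal(60) for _ in range(4)]
        trials.append(base + 5.0)  # gross outlier
        assert select_reference(trials, "medoid") != 4

    def test_medoid_deterministic_across_runs(self, processed12):
        vels = processed12.velocities
        assert select_reference(vels, "medoid") == select_reference(vels, "medoid")

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            select_reference([np.zeros(5)], "medoid")

    def test_index_strategy_validates(self):
        v = [np.zeros(5), np.ones(5)]
        assert select_reference(v, "index", index=1) == 1
        with pytest.raises(ValueError):
            select_reference(v, "index", index=7)


class TestConventionalAverage:
    def test_identical_trials_average_to_themselves(self, rng):
        v = rng.standard_normal((40, 8))
        avg = conventional_average([make_norm(v), make_norm(v.copy())])
        assert np.allclose(avg.values, v)

    def test_opposite_deviations_average_to_midpoint(self, rng):
        base = rng.standard_normal((40, 8))
        d = rng.standard_normal((40, 8))
        avg = conventional_average([make_norm(base + d), make_norm(base - d)])
        assert np.allclose(avg.values, base)

    def test_grid_mismatch_rejected(self, rng):
        a = make_norm(rng.standard_normal((40, 8)))
        b = make_norm(rng.standard_normal((41, 8)))
        with pytest.raises(ValueError):
            conventional_average([a, b])

    def test_jitter_smears_the_average_peak(self, rng):
        # gamma-like bursts at jittered latencies: the averaged peak is lower
        # than the mean of the per-trial peaks
        ft = np.arange(200) * 0.01
        specs = []
        for _ in range(12):
            c = 1.0 + rng.normal(0, 0.25)
            specs.append(make_norm(np.tile(bump(ft, c)[:, None], (1, 5))))
        avg = conventional_average(specs)
        mean_of_peaks = np.mean([s.values[:, 0].max() for s in specs])
        assert avg.values[:, 0].max() < mean_of_peaks - 1.0


class TestWarpedAverage:
    def test_identical_trials_equal_conventional(self, rng):
        v = rng.standard_normal((60, 6))
        vel = np.sin(np.arange(60) / 8.0)
        specs = [make_norm(v), make_norm(v.copy()), make_norm(v.copy())]
        warped = warped_average(specs, [vel, vel.copy(), vel.copy()], reference=0)
        conv = conventional_average(specs)
        assert np.array_equal(warped.values, conv.values)

    def test_missing_kinematics_reported(self, rng):
        specs = [make_norm(rng.standard_normal((60, 6))) for _ in range(3)]
        with pytest.raises(ValueError, match="missing kinematics"):
            warped_average(specs, [np.zeros(60)], reference=0)

    def test_two_trial_session_uses_both(self, rng):
        v = rng.standard_normal((60, 6))
        vel = np.sin(np.arange(60) / 8.0)
        warped = warped_average([make_norm(v), make_norm(v + 2.0)], [vel, vel], 0)
        assert np.allclose(warped.values, v + 1.0)


class TestRmsError:
    def test_worked_examples(self):
        a = make_norm(np.zeros((2, 2)))
        assert rms_error(a, a) == 0.0
        assert rms_error(a, make_norm(np.full((2, 2), 3.0))) == pytest.approx(3.0)
        assert rms_error(a, make_norm(np.ones((2, 2)))) == pytest.approx(1.0)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(100):
            x, y, z = (make_norm(rng.standard_normal((6, 4))) for _ in range(3))
            assert rms_error(x, y) == pytest.approx(rms_error(y, x))
            assert rms_error(x, x) == 0.0
            assert rms_error(x, z) <= rms_error(x, y) + rms_error(y, z) + 1e-12

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rms_error(make_norm(np.zeros((2, 2))), make_norm(np.zeros((3, 2))))


class TestBandChangeKs:
    def test_default_session_directions(self, processed12):
        specs = processed12.norm_specs
        p_g, dir_g = band_change_ks_test(specs, (65.0, 140.0))
        p_b, dir_b = band_change_ks_test(specs, (12.0, 30.0))
        assert dir_g == 1 and dir_b == -1
        assert p_g < 0.05 and p_b < 0.05

    def test_single_trial_rejected(self, processed12):
        with pytest.raises(ValueError):
            band_change_ks_test(processed12.norm_specs[:1], (65.0, 140.0))

    def test_empty_window_rejected(self, processed12):
        with pytest.raises(ValueError):
            band_change_ks_test(
                processed12.norm_specs, (65.0, 140.0), movement_window=(20.0, 21.0)
            )


class TestAverageRectifiedEmg:
    def test_zero_signals_average_to_zero(self):
        out = average_rectified_emg([np.zeros(100)] * 3, "onset")
        assert np.array_equal(out, np.zeros(100))

    def test_identical_bursts_average_to_single_burst(self, rng):
        burst = rng.standard_normal(100)
        out = average_rectified_emg([burst, burst.copy()], "onset")
        assert np.allclose(out, np.abs(burst))

    def test_warped_average_retains_burst_end_amplitude(self, processed12, session12):
        # onset-aligned averaging washes out the end of jittered-duration
        # bursts; path-based warping keeps it sharp
        trials = processed12.trials
        ref = select_reference(processed12.velocities, "medoid")
        paths = [
            None if i == ref else dtw_path(trials[ref].velocity.vx, t.velocity.vx)
            for i, t in enumerate(trials)
        ]
        emgs = [t.emg for t in trials]
        onset_avg = average_rectified_emg(emgs, "onset")
        warped_avg = average_rectified_emg(emgs, "paths", paths=paths)
        ft = trials[ref].norm.frame_times
        # reference trial's reach end, in time relative to its onset
        src = session12.trials[trials[ref].trial_id]
        end_rel = src.true_phase_boundaries[0] - src.true_onset
        from ecogwarp.ensemble import frame_rectified

        ref_frames = frame_rectified(trials[ref].emg, 120, 12)
        w_end = np.flatnonzero((ft >= end_rel - 0.25) & (ft < end_rel - 0.05))
        warped_level = warped_avg[w_end].mean()
        single_level = ref_frames[w_end].mean()
        assert warped_level >= 0.8 * single_level
        # and the quiet period between reach and retrieval stays quiet after
        # warping, while onset alignment fills it with residual activity
        pause_start = end_rel + 0.15
        pause_end = (src.true_phase_boundaries[1] - src.true_onset) - 0.15
        p_mask = (ft >= pause_start) & (ft < pause_end)
        t_sig = -4.0 + np.arange(onset_avg.size) / 1200.0
        o_mask = (t_sig >= pause_start) & (t_sig < pause_end)
        assert warped_avg[p_mask].mean() < onset_avg[o_mask].mean()

    def test_paths_alignment_requires_paths(self):
        with pytest.raises(ValueError):
            average_rectified_emg([np.zeros(100)] * 2, "paths")


class TestPermutationEvaluation:
    def test_identical_trials_degenerate(self, rng):
        v = rng.standard_normal((60, 6))
        vel = np.sin(np.arange(60) / 8.0)
        specs = [make_norm(v), make_norm(v.copy()), make_norm(v.copy())]
        with pytest.raises(ValueError, match="degenerate"):
            permutation_evaluation(specs, [vel] * 3, force_identity_paths=True)

    def test_identity_paths_are_null_calibrated(self, processed12):
        ev = permutation_evaluation(
            processed12.norm_specs, processed12.velocities, force_identity_paths=True
        )
        assert ev.p_value >= 0.05
        assert np.array_equal(ev.warped_errors, ev.unwarped_errors)

    def test_jittered_session_shows_warping_benefit(self, processed12):
        ev = permutation_evaluation(processed12.norm_specs, processed12.velocities)
        assert ev.p_value < 0.01
        assert ev.t_statistic < 0
        assert len(ev.pair_ids) == 12 * 11

    def test_too_few_trials_rejected(self, processed12):
        with pytest.raises(ValueError):
            permutation_evaluation(
                processed12.norm_specs[:2], processed12.velocities[:2]
            )

    def test_separation_grows_with_onset_misalignment(self):
        # cue-locked (fixed-time) epochs: the larger the onset jitter, the
        # further apart the warped and unwarped log-error distributions
        from ecogwarp import RunConfig, baseline_normalize, compute_spectrogram
        from ecogwarp.containers import SignalTrace
        from ecogwarp.kinematics import compute_velocity, extract_epoch, resample_to_frames

        seps = []
        for jitter in (0.02, 0.15, 0.4):
            params = SessionParams(
                n_trials=8,
                seed=55,
                onset_jitter_sd=jitter,
                reach_duration_sd=0.05,
                pause_duration_sd=0.05,
                retrieve_duration_sd=0.05,
            )
            sess = generate_session(params, with_templates=False)
            specs, vels = [], []
            for tr in sess.trials:
                trial = extract_epoch(
                    tr.ecog, tr.kinematics, NOMINAL_ONSET_S, emg=tr.emg
                )
                spec = compute_spectrogram(trial.ecog, fmax=200.0)
                specs.append(baseline_normalize(spec))
                vel = compute_velocity(trial.kinematics)
                vels.append(resample_to_frames(vel, spec.frame_times))
            ev = permutation_evaluation(specs, vels)
            seps.append(float(np.mean(ev.log_unwarped) - np.mean(ev.log_warped)))
        assert seps[0] < seps[1] < seps[2]


class TestKinematicWarpErrorReport:
    def test_identical_kinematics_give_zero_errors(self):
        v = np.sin(np.arange(60) / 8.0)
        rep = kinematic_warp_error_report([v, v.copy(), v.copy()])
        assert rep["median"] == 0.0 and np.all(rep["pair_errors"] == 0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            kinematic_warp_error_report([np.zeros(10)])

    def test_overshooting_sessions_have_larger_residuals(self):
        medians = {}
        for prob in (0.0, 0.4):
            params = SessionParams(n_trials=10, seed=66, overshoot_prob=prob)
            proc = process_session(generate_session(params, with_templates=False))
            medians[prob] = kinematic_warp_error_report(proc.velocities)["median"]
        assert medians[0.4] > medians[0.0]
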