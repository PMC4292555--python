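"""Across-trial ensemble operations: conventional and time-warped averaging
of normalized spectrograms, rectified-EMG averages, the band-change
Kolmogorov-Smirnov test, and the permutation RMS-error evaluation.

The evaluation permutes the reference ("gold-standard") trial across all
trials: for every ordered (reference, query) pair the RMS difference over
all time-frequency cells is computed once with the query warped along the
kinematics-derived path and once at plain onset alignment.  The unwarped
errors form the null distribution; because log RMS errors are close to
normal, a one-sided Welch t-test on the log samples quantifies whether
warping reduced spectrogram variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import VelocitySeries
from .tfr import NormalizedSpectrogram, band_power
from .warp import RegistrationPath, dtw_cost, dtw_path, warp_series, warp_spectrogram

__all__ = [
    "ErrorDistributions",
    "select_reference",
    "conventional_average",
    "warped_average",
    "average_rectified_emg",
    "band_change_ks_test",
    "rms_error",
    "permutation_evaluation",
    "kinematic_warp_error_report",
]


@dataclass
class ErrorDistributions:
    """Paired warped/unwarped RMS-error samples and the log-domain t-test.

    ``warped_errors[k]`` and ``unwarped_errors[k]`` come from the same
    ordered (reference, query) pair ``pair_ids[k]``.  Pairs with a zero
    error (log undefined) are excluded from the test but reported in
    ``excluded_pairs``, never silently dropped.
    """

    warped_errors: np.ndarray
    unwarped_errors: np.ndarray
    pair_ids: list[tuple[int, int]]
    t_statistic: float
    p_value: float
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def log_warped(self) -> np.ndarray:
        return np.log(self.warped_errors)

    @property
    def log_unwarped(self) -> np.ndarray:
        return np.log(self.unwarped_errors)


def _velocity_array(v) -> np.ndarray:
    return np.asarray(v.vx if isinstance(v, VelocitySeries) else v, dtype=float)


def select_reference(
    velocities: list, strategy: str = "medoid", index: int | None = None
):
    """Choose the reference ("gold-standard") trial(s).

    ``medoid`` picks the trial minimizing the summed normalized DTW cost to
    all other trials (the most central movement); ``index`` uses a fixed
    user-chosen trial; ``permute_all`` returns every index in turn, as used
    by :func:`permutation_evaluation`.
    """
    n = len(velocities)
    if n < 2:
        raise ValueError("need at least 2 trials to select a reference")
    if strategy == "index":
        if index is None or not (0 <= index < n):
            raise ValueError("strategy 'index' requires a valid trial index")
        return index
    if strategy == "permute_all":
        return list(range(n))
    if strategy != "medoid":
        raise ValueError(f"unknown reference strategy {strategy!r}")
    arrs = [_velocity_array(v) for v in velocities]
    costs = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = dtw_cost(arrs[i], arrs[j]) / (arrs[i].size + arrs[j].size)
            costs[i, j] = costs[j, i] = c
    return int(np.argmin(costs.sum(axis=1)))


def _check_grids(specs: list[NormalizedSpectrogram]) -> None:
    f0, t0 = specs[0].freqs, specs[0].frame_times
    for s in specs[1:]:
        if s.freqs.shape != f0.shape or s.frame_times.shape != t0.shape or not (
            np.allclose(s.freqs, f0) and np.allclose(s.frame_times, t0)
        ):
            raise ValueError("spectrogram grids differ across trials")


def conventional_average(norm_specs: list[NormalizedSpectrogram]) -> NormalizedSpectrogram:
    """Cell-wise mean of onset-aligned normalized spectrograms.

    This is the standard way of averaging trial spectrograms; with variable
    movement durations it smears movement-related components along time.
    """
    if not norm_specs:
        raise ValueError("no spectrograms to average")
    _check_grids(norm_specs)
    mean = np.mean([s.values for s in norm_specs], axis=0)
    return NormalizedSpectrogram(
        frame_times=norm_specs[0].frame_times.copy(),
        freqs=norm_specs[0].freqs.copy(),
        values=mean,
        baseline_window=norm_specs[0].baseline_window,
    )


def warped_average(
    norm_specs: list[NormalizedSpectrogram],
    velocities: list,
    reference: int,
    warp_on: str = "vx",
) -> NormalizedSpectrogram:
    """Time-warped average: align every trial to the reference, then average.

    For each non-reference trial the registration path is computed by DTW
    between the reference and trial velocity profiles (signed X velocity by
    default, ``warp_on="speed"`` for the magnitude), applied to the trial's
    normalized spectrogram, and the cell-wise mean taken including the
    untouched reference.
    """
    if len(norm_specs) != len(velocities):
        missing = list(range(len(norm_specs)))[len(velocities):]
        raise ValueError(f"missing kinematics for trials {missing}")
    _check_grids(norm_specs)
    ref_v = _series_for_warp(velocities[reference], warp_on)
    acc = norm_specs[reference].values.copy()
    for q in range(len(norm_specs)):
        if q == reference:
            continue
        path = dtw_path(ref_v, _series_for_warp(velocities[q], warp_on))
        acc += warp_spectrogram(norm_specs[q], path).values
    return NormalizedSpectrogram(
        frame_times=norm_specs[reference].frame_times.copy(),
        freqs=norm_specs[reference].freqs.copy(),
        values=acc / len(norm_specs),
        baseline_window=norm_specs[reference].baseline_window,
    )


def _series_for_warp(v, warp_on: str) -> np.ndarray:
    if isinstance(v, VelocitySeries):
        if warp_on == "vx":
            return v.vx
        if warp_on == "speed":
            return v.speed
        raise ValueError("warp_on must be 'vx' or 'speed'")
    return np.asarray(v, dtype=float)


def frame_rectified(emg_data: np.ndarray, n_win: int, hop: int) -> np.ndarray:
    """Mean rectified amplitude per spectrogram frame (same framing as STFT)."""
    from numpy.lib.stride_tricks import sliding_window_view

    frames = sliding_window_view(np.asarray(emg_data, dtype=float), n_win)[::hop]
    return np.abs(frames).mean(axis=1)


def average_rectified_emg(
    emg_trials: list[np.ndarray],
    alignment: str = "onset",
    paths: list[RegistrationPath | None] | None = None,
    n_win: int = 120,
    hop: int = 12,
) -> np.ndarray:
    """Across-trial average of rectified EMG.

    With ``alignment="onset"`` the full-rate rectified signals are averaged
    sample-wise.  With ``alignment="paths"`` each trial is first reduced to
    mean rectified amplitude per spectrogram frame and warped along its
    registration path (``None`` for the reference trial), so the average
    shares the time base of the warped spectrograms; this keeps the sharp
    fall at movement end that onset alignment washes out.
    """
    if not emg_trials:
        raise ValueError("no EMG trials")
    if alignment == "onset":
        lens = {np.asarray(e).size for e in emg_trials}
        if len(lens) != 1:
            raise ValueError("EMG trials differ in length")
        return np.mean([np.abs(np.asarray(e, dtype=float)) for e in emg_trials], axis=0)
    if alignment != "paths":
        raise ValueError("alignment must be 'onset' or 'paths'")
    if paths is None or len(paths) != len(emg_trials):
        raise ValueError("alignment 'paths' requires one path (or None) per trial")
    out = []
    for e, p in zip(emg_trials, paths):
        series = frame_rectified(np.asarray(e, dtype=float), n_win, hop)
        out.append(series if p is None else warp_series(series, p))
    lens = {o.size for o in out}
    if len(lens) != 1:
        raise ValueError("warped EMG series differ in length")
    return np.mean(out, axis=0)


def band_change_ks_test(
    norm_specs: list[NormalizedSpectrogram],
    band: tuple[float, float],
    movement_window: tuple[float, float] = (0.0, 1.0),
    baseline_window: tuple[float, float] = (-2.0, -1.0),
) -> tuple[float, int]:
    """Two-sample KS test for a movement-related band-power change.

    Per trial, the mean normalized band value is taken in the movement
    window and in the baseline window; the two across-trial samples are
    compared with a two-sample Kolmogorov-Smirnov test.  Returns
    ``(p_value, direction)`` with direction the sign of the mean
    movement-minus-baseline difference (+1 for an ERS, -1 for an ERD).
    """
    if len(norm_specs) < 2:
        raise ValueError("need at least 2 trials")
    _check_grids(norm_specs)
    t = norm_specs[0].frame_times
    m_mask = (t >= movement_window[0]) & (t < movement_window[1])
    b_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not m_mask.any() or not b_mask.any():
        raise ValueError("empty movement or baseline window")
    mov, base = [], []
    for s in norm_specs:
        series = band_power(s, band)
        mov.append(series[m_mask].mean())
        base.append(series[b_mask].mean())
    mov, base = np.asarray(mov), np.asarray(base)
    res = stats.ks_2samp(mov, base)
    direction = int(np.sign(mov.mean() - base.mean())) or 1
    return float(res.pvalue), direction


def rms_error(a: NormalizedSpectrogram, b: NormalizedSpectrogram) -> float:
    """Root-mean-square difference over all time-frequency cells.

    Normalized by the cell count (root of the *mean* square) so values are
    comparable across grid sizes.  A true metric on a fixed grid.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("spectrogram grids differ")
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


def permutation_evaluation(
    norm_specs: list[NormalizedSpectrogram],
    velocities: list,
    warp_on: str = "vx",
    force_identity_paths: bool = False,
    paired: bool = False,
) -> ErrorDistributions:
    """Permute the reference across all trials and test the warping benefit.

    For every ordered (reference r, query q) pair, ``warped_error`` is the
    RMS between the reference spectrogram and the query spectrogram warped
    along the kinematic path, and ``unwarped_error`` the RMS at plain onset
    alignment (the null).  Both log-error samples enter a one-sided Welch
    t-test (warped < unwarped); ``paired=True`` uses the paired t-test on
    the log differences instead.

    ``force_identity_paths`` replaces every path by the identity — a
    calibration mode in which warping cannot help and the test must come
    out non-significant.
    """
    n = len(norm_specs)
    if n < 3:
        raise ValueError("need at least 3 trials for the permutation evaluation")
    if len(velocities) != n:
        raise ValueError("one velocity series per spectrogram is required")
    _check_grids(norm_specs)
    if not all(np.isfinite(s.values).all() for s in norm_specs):
        raise ValueError("non-finite spectrogram cells")

    warped, unwarped, pair_ids, excluded = [], [], [], []
    for r in range(n):
        ref_spec = norm_specs[r]
        ref_v = _series_for_warp(velocities[r], warp_on)
        for q in range(n):
            if q == r:
                continue
            if force_identity_paths:
                w_spec = norm_specs[q]
            else:
                path = dtw_path(ref_v, _series_for_warp(velocities[q], warp_on))
                w_spec = warp_spectrogram(norm_specs[q], path)
            we = rms_error(ref_spec, w_spec)
            ue = rms_error(ref_spec, norm_specs[q])
            if we <= 0.0 or ue <= 0.0:
                excluded.append((r, q))
                continue
            warped.append(we)
            unwarped.append(ue)
            pair_ids.append((r, q))
    if not warped:
        raise ValueError(
            "degenerate error distributions: every pair has zero RMS error "
            f"({len(excluded)} pairs excluded)"
        )
    warped = np.asarray(warped)
    unwarped = np.asarray(unwarped)
    lw, lu = np.log(warped), np.log(unwarped)
    if paired:
        res = stats.ttest_rel(lw, lu, alternative="less")
    else:
        res = stats.ttest_ind(lw, lu, equal_var=False, alternative="less")
    t_stat = float(res.statistic)
    p_val = float(res.pvalue)
    if np.isnan(t_stat):  # identical constant samples
        t_stat, p_val = 0.0, 0.5
    return ErrorDistributions(
        warped_errors=warped,
        unwarped_errors=unwarped,
        pair_ids=pair_ids,
        t_statistic=t_stat,
        p_value=p_val,
        excluded_pairs=excluded,
    )


def kinematic_warp_error_report(
    velocities: list, warp_on: str = "vx"
) -> dict:
    """RMS error from warping the kinematic trajectories alone.

    For every ordered (reference, query) pair the query velocity is warped
    onto the reference axis and the RMS residual computed.  A session whose
    median residual is large (e.g. because the subject overshot the target,
    adding a corrective reversal the other trials lack) is one where
    kinematic warping is unreliable and warped averages should be read with
    care.  Returns per-pair errors plus median/mean summaries.
    """
    n = len(velocities)
    if n < 2:
        raise ValueError("need at least 2 trials")
    arrs = [_series_for_warp(v, warp_on) for v in velocities]
    errors = np.empty((n, n))
    np.fill_diagonal(errors, 0.0)
    for r in range(n):
        for q in range(n):
            if q == r:
                continue
            path = dtw_path(arrs[r], arrs[q])
            w = warp_series(arrs[q], path)
            errors[r, q] = np.sqrt(np.mean((arrs[r] - w) ** 2))
    off_diag = errors[~np.eye(n, dtype=bool)]
    return {
        "pair_errors": errors,
        "median": float(np.median(off_diag)),
        "mean": float(np.mean(off_diag)),
        "per_trial_mean": errors.sum(axis=1) / (n - 1),
    }
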