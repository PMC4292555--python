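"""Seeded synthetic reach/pause/retrieve sessions: kinematics, ECoG and EMG
with the statistical structure that kinematics-guided time-warped averaging
assumes.

Each trial emulates a seated reach to a target 40 cm from the chest,
followed by a pause and a self-paced retrieval.  Per-phase durations are
drawn from normal distributions (defaults: reach 1.2 +/- 0.3 s, pause
1.3 +/- 0.4 s, retrieval 1.0 +/- 0.3 s) truncated at mean +/- 3 sd, and the
movement start is jittered relative to the auditory cue.  Arm speed follows
a minimum-jerk (quintic) profile per phase — the standard model of
point-to-point reaching — with an optional target overshoot that appends a
corrective reversal.

The ECoG channel is 1/f-shaped broadband noise plus a beta-band (12-30 Hz)
oscillation whose envelope is multiplicatively suppressed while the arm
moves (ERD) and gamma-band (65-140 Hz) noise whose instantaneous power
grows linearly with arm speed (ERS), optionally plus a mains sinusoid.  The
EMG channel is a zero-mean broadband burst whose amplitude is proportional
to speed, silent at rest apart from a sensor-noise floor.  Every trial
carries its analytic ground truth (onset, phase boundaries and the expected
normalized spectrogram) so the whole pipeline is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .containers import SignalTrace
from .kinematics import KinematicTrace
from .tfr import NormalizedSpectrogram

__all__ = [
    "SessionParams",
    "SyntheticTrial",
    "SyntheticSession",
    "gen_velocity_profile",
    "gen_ecog_from_velocity",
    "gen_emg_from_velocity",
    "generate_session",
    "epoch_frame_times",
]

# fixed conventions of the simulated protocol
TRIAL_LENGTH_S = 15.0          # per-trial recording extent
NOMINAL_ONSET_S = 5.0          # movement start before jitter
REACTION_TIME_S = 0.5          # cue precedes movement start by this much
ONSET_SPEED_THRESHOLD = 0.5    # cm/s, the movement-onset convention
_Y_SLOPE, _Z_SLOPE = 0.08, 0.05  # small off-axis components of the reach
_SPEED_3D_FACTOR = float(np.sqrt(1.0 + _Y_SLOPE**2 + _Z_SLOPE**2))
_OVERSHOOT_FRACTION = 0.15     # overshoot distance as a fraction of amplitude
_CORRECTIVE_DURATION_S = 0.35  # duration of the corrective reversal
_BETA_POWER_RATIO = 4.0        # beta PSD relative to background at band center
_EMG_NOISE_FLOOR = 1.0         # a.u., rest-state sensor noise
_EMG_GAIN = 2.0                # a.u. per cm/s of arm speed


class ParameterError(ValueError):
    """Invalid synthetic-session parameters."""


@dataclass
class SessionParams:
    """Generator settings; the defaults are the simulated study conditions.

    Duration statistics default to the first participant row of the task
    summary (reach 1.2 +/- 0.3 s, pause 1.3 +/- 0.4 s, retrieval
    1.0 +/- 0.3 s); ``reach_amplitude`` is the 40 cm chest-to-target
    distance.  ``erd_depth`` is the multiplicative beta-amplitude factor
    during movement (0.5 -> power drops to 25 %); ``ers_gain`` scales the
    added gamma power per cm/s of arm speed, expressed relative to the
    background level at the gamma band center.  Line noise is off by
    default; 60 Hz is the conventional choice when enabled.
    """

    n_trials: int = 50
    reach_duration_mean: float = 1.2
    reach_duration_sd: float = 0.3
    pause_duration_mean: float = 1.3
    pause_duration_sd: float = 0.4
    retrieve_duration_mean: float = 1.0
    retrieve_duration_sd: float = 0.3
    onset_jitter_sd: float = 0.3
    reach_amplitude: float = 40.0
    overshoot_prob: float = 0.0
    kin_rate: float = 40.0
    sig_rate: float = 1200.0
    beta_band: tuple[float, float] = (12.0, 30.0)
    gamma_band: tuple[float, float] = (65.0, 140.0)
    erd_depth: float = 0.5
    ers_gain: float = 0.1
    line_noise_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        for name in ("reach", "pause", "retrieve"):
            mean = getattr(self, f"{name}_duration_mean")
            sd = getattr(self, f"{name}_duration_sd")
            if sd < 0 or mean <= 0:
                raise ParameterError(f"{name} duration mean/sd out of range")
            if mean - 3.0 * sd <= 0:
                raise ParameterError(
                    f"{name} duration mean - 3 sd must stay positive "
                    f"(got {mean} +/- {sd}); the truncation floor would vanish"
                )
        if not (0.0 <= self.overshoot_prob <= 1.0):
            raise ParameterError("overshoot_prob must lie in [0, 1]")
        if self.onset_jitter_sd < 0:
            raise ParameterError("onset_jitter_sd must be >= 0")
        if self.reach_amplitude <= 0:
            raise ParameterError("reach_amplitude must be positive")
        if self.kin_rate <= 0 or self.sig_rate <= 0:
            raise ParameterError("sampling rates must be positive")
        nyq = self.sig_rate / 2.0
        for bname in ("beta_band", "gamma_band"):
            lo, hi = getattr(self, bname)
            if not (0.0 < lo < hi < nyq):
                raise ParameterError(
                    f"{bname} {(lo, hi)} must be a non-empty interval in (0, {nyq})"
                )
        if not (0.0 <= self.erd_depth):
            raise ParameterError("erd_depth must be >= 0")
        if self.ers_gain < 0:
            raise ParameterError("ers_gain must be >= 0")
        if self.line_noise_hz is not None and not (0 < self.line_noise_hz < nyq):
            raise ParameterError("line_noise_hz must lie below Nyquist")


@dataclass
class _MinJerkSegment:
    t_start: float
    duration: float
    x0: float
    x1: float

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def position(self, t: np.ndarray) -> np.ndarray:
        tau = np.clip((t - self.t_start) / self.duration, 0.0, 1.0)
        return self.x0 + (self.x1 - self.x0) * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)

    def vx(self, t: np.ndarray) -> np.ndarray:
        tau = (t - self.t_start) / self.duration
        inside = (tau > 0) & (tau < 1)
        tau = np.clip(tau, 0.0, 1.0)
        v = (self.x1 - self.x0) / self.duration * 30.0 * tau**2 * (1.0 - tau) ** 2
        return np.where(inside, v, 0.0)


@dataclass
class _TrialPlan:
    """Analytic description of one trial's movement.

    ``t0`` is where the minimum-jerk reach leaves zero; ``onset`` and the
    phase boundaries are where the analytic 3-D speed crosses the 0.5 cm/s
    convention, i.e. the instants an ideal threshold detector would report.
    The drawn phase durations are kept so distributional checks can use the
    exact sampled values rather than threshold-shaved estimates.
    """

    t0: float                      # reach segment start, absolute seconds
    segments: list[_MinJerkSegment]
    onset: float                   # first 0.5 cm/s up-crossing
    reach_end: float               # last down-crossing before the pause
    retrieve_start: float
    retrieve_end: float
    cue_time: float
    overshoot: bool
    reach_duration: float = 0.0
    pause_duration: float = 0.0
    retrieve_duration: float = 0.0

    def position_x(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.zeros_like(t)
        for seg in self.segments:
            x = np.where(t >= seg.t_start, seg.position(t), x)
        return x

    def vx(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        for seg in self.segments:
            v = v + seg.vx(t)
        return v

    def speed(self, t: np.ndarray) -> np.ndarray:
        """3-D speed magnitude (X velocity scaled by the off-axis factor)."""
        return np.abs(self.vx(t)) * _SPEED_3D_FACTOR


@dataclass
class SyntheticTrial:
    """One generated trial plus the ground truth used only for testing."""

    trial_id: int
    kinematics: KinematicTrace
    ecog: SignalTrace
    emg: SignalTrace
    cue_time: float
    true_onset: float
    true_phase_boundaries: tuple[float, float, float]
    ground_truth_template: NormalizedSpectrogram | None = None
    plan: _TrialPlan | None = None


@dataclass
class SyntheticSession:
    params: SessionParams
    trials: list[SyntheticTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)


def _trial_seed(params: SessionParams, trial_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(params.seed), int(trial_index)])


def _trial_rngs(params: SessionParams, trial_index: int):
    kin_ss, ecog_ss, emg_ss = _trial_seed(params, trial_index).spawn(3)
    return (
        np.random.default_rng(kin_ss),
        np.random.default_rng(ecog_ss),
        np.random.default_rng(emg_ss),
    )


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated (by rejection) to mean +/- 3 sd.

    Symmetric truncation keeps the sample mean unbiased; the lower bound
    doubles as the positivity floor guaranteed by parameter validation.
    """
    if sd == 0.0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3.0 * sd:
            return x


def _draw_plan(params: SessionParams, rng: np.random.Generator) -> _TrialPlan:
    jitter = _draw_truncated(rng, 0.0, params.onset_jitter_sd)
    t_reach = _draw_truncated(rng, params.reach_duration_mean, params.reach_duration_sd)
    t_pause = _draw_truncated(rng, params.pause_duration_mean, params.pause_duration_sd)
    t_ret = _draw_truncated(
        rng, params.retrieve_duration_mean, params.retrieve_duration_sd
    )
    overshoot = bool(rng.random() < params.overshoot_prob)

    t0 = NOMINAL_ONSET_S + jitter
    a = params.reach_amplitude
    segments = []
    t = t0
    if overshoot:
        top = a * (1.0 + _OVERSHOOT_FRACTION)
        segments.append(_MinJerkSegment(t, t_reach, 0.0, top))
        t += t_reach
        segments.append(_MinJerkSegment(t, _CORRECTIVE_DURATION_S, top, a))
        t += _CORRECTIVE_DURATION_S
    else:
        segments.append(_MinJerkSegment(t, t_reach, 0.0, a))
        t += t_reach
    reach_end = t
    t += t_pause
    segments.append(_MinJerkSegment(t, t_ret, a, 0.0))
    retrieve_end_nominal = t + t_ret
    if retrieve_end_nominal > TRIAL_LENGTH_S - 1.0:
        raise ParameterError("movement does not fit the trial extent")
    plan = _TrialPlan(
        t0=t0,
        segments=segments,
        onset=t0,
        reach_end=reach_end,
        retrieve_start=t,
        retrieve_end=retrieve_end_nominal,
        cue_time=t0 - REACTION_TIME_S,
        overshoot=overshoot,
        reach_duration=t_reach,
        pause_duration=t_pause,
        retrieve_duration=t_ret,
    )
    _refine_boundaries(plan)
    return plan


def _refine_boundaries(plan: _TrialPlan, dt: float = 1e-3) -> None:
    """Snap onset and phase boundaries to 0.5 cm/s crossings of the
    analytic speed, evaluated on a 1 ms grid (well below any tolerance the
    downstream bookkeeping uses)."""
    tt = np.arange(plan.t0 - 0.05, plan.retrieve_end + 0.05, dt)
    moving = plan.speed(tt) > ONSET_SPEED_THRESHOLD
    edges = np.flatnonzero(np.diff(moving.astype(np.int8)))
    starts = [tt[e + 1] for e in edges[::2]]
    ends = [tt[e] for e in edges[1::2]]
    if len(starts) < 2 or len(starts) != len(ends):
        raise RuntimeError("unexpected speed-run structure in synthetic plan")
    plan.onset = float(starts[0])
    plan.reach_end = float(ends[-2])   # last run before retrieval
    plan.retrieve_start = float(starts[-1])
    plan.retrieve_end = float(ends[-1])


def _plan_to_trace(plan: _TrialPlan, params: SessionParams) -> KinematicTrace:
    n = int(round(TRIAL_LENGTH_S * params.kin_rate))
    t = np.arange(n) / params.kin_rate
    x = plan.position_x(t)
    return KinematicTrace(
        timestamps=t, position=np.column_stack([x, _Y_SLOPE * x, _Z_SLOPE * x])
    )


def gen_velocity_profile(
    params: SessionParams,
    trial_index: int,
    seed_stream: np.random.Generator | None = None,
) -> KinematicTrace:
    """Generate one trial's noiseless 3-D hand-position trace.

    The outward phase displaces X by ``reach_amplitude`` (plus an optional
    overshoot-and-correct reversal) and the retrieval returns it to the
    start; per-phase durations are truncated-normal draws.  Deterministic
    given ``params.seed`` and ``trial_index`` when no explicit random
    generator is passed.
    """
    rng = seed_stream if seed_stream is not None else _trial_rngs(params, trial_index)[0]
    plan = _draw_plan(params, rng)
    return _plan_to_trace(plan, params)


def _kin_speed_at_sig_rate(kin: KinematicTrace, sig_rate: float) -> np.ndarray:
    """3-D speed from positions, linearly resampled to the signal rate."""
    vel = np.gradient(kin.position, kin.timestamps, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    n = int(round((kin.timestamps[-1] - kin.timestamps[0] + 1.0 / kin.rate) * sig_rate))
    t_sig = kin.timestamps[0] + np.arange(n) / sig_rate
    return np.interp(t_sig, kin.timestamps, speed), t_sig


def _psd_background(f: np.ndarray) -> np.ndarray:
    """1/f power shape with a flat floor below 1 Hz (arbitrary units)."""
    return 1.0 / np.maximum(np.asarray(f, dtype=float), 1.0)


def _band_psd_level(band: tuple[float, float], ratio: float) -> float:
    fc = 0.5 * (band[0] + band[1])
    return ratio * float(_psd_background(np.array([fc]))[0])


def _colored_noise(
    rng: np.random.Generator, n: int, rate: float, psd: np.ndarray
) -> np.ndarray:
    """Gaussian noise with the given one-sided PSD shape via spectral synthesis."""
    amp = np.sqrt(psd)
    z = rng.standard_normal(amp.size) + 1j * rng.standard_normal(amp.size)
    spec = amp * z
    spec[0] = 0.0
    return np.fft.irfft(spec, n) * np.sqrt(n / 2.0)


def _smooth_gate(indicator: np.ndarray, rate: float, width_s: float = 0.1) -> np.ndarray:
    w = get_window("hann", max(int(round(width_s * rate)), 3))
    w = w / w.sum()
    return np.clip(np.convolve(indicator.astype(float), w, mode="same"), 0.0, 1.0)


def gen_ecog_from_velocity(
    kin: KinematicTrace,
    params: SessionParams,
    seed_stream: np.random.Generator,
) -> SignalTrace:
    """Synthesize a bipolar ECoG channel driven by the arm speed.

    The output is the sum of 1/f background noise, a beta-band oscillation
    whose envelope is multiplied by ``erd_depth`` while the arm moves
    (smoothly gated at the 0.5 cm/s speed threshold), gamma-band noise whose
    instantaneous power is ``ers_gain * speed`` times the background level
    at the gamma band center, and an optional mains sinusoid.  Amplitude
    modulations are computed on the kinematic grid and resampled to
    ``sig_rate``.
    """
    nyq = params.sig_rate / 2.0
    if params.gamma_band[1] >= nyq or params.beta_band[1] >= nyq:
        raise ParameterError("modulation band overlaps Nyquist")
    speed_sig, t_sig = _kin_speed_at_sig_rate(kin, params.sig_rate)
    n = speed_sig.size
    freqs = np.fft.rfftfreq(n, 1.0 / params.sig_rate)

    bg = _colored_noise(seed_stream, n, params.sig_rate, _psd_background(freqs))

    beta_psd = np.where(
        (freqs >= params.beta_band[0]) & (freqs <= params.beta_band[1]),
        _band_psd_level(params.beta_band, _BETA_POWER_RATIO),
        0.0,
    )
    beta = _colored_noise(seed_stream, n, params.sig_rate, beta_psd)
    gate = _smooth_gate(speed_sig > ONSET_SPEED_THRESHOLD, params.sig_rate)
    envelope = 1.0 - (1.0 - params.erd_depth) * gate
    beta *= envelope

    gamma_psd = np.where(
        (freqs >= params.gamma_band[0]) & (freqs <= params.gamma_band[1]),
        _band_psd_level(params.gamma_band, 1.0),
        0.0,
    )
    gamma = _colored_noise(seed_stream, n, params.sig_rate, gamma_psd)
    gamma *= np.sqrt(np.maximum(params.ers_gain * speed_sig, 0.0))

    data = bg + beta + gamma
    if params.line_noise_hz is not None:
        a_line = 2.0 * float(np.std(bg))
        phase = seed_stream.uniform(0.0, 2.0 * np.pi)
        data = data + a_line * np.sin(2.0 * np.pi * params.line_noise_hz * t_sig + phase)
    return SignalTrace(data=data, rate=params.sig_rate, t0=float(t_sig[0]), name="ecog")


def gen_emg_from_velocity(
    kin: KinematicTrace,
    params: SessionParams,
    seed_stream: np.random.Generator,
) -> SignalTrace:
    """Synthesize a rectifiable EMG burst gated by arm speed.

    Zero-mean white noise whose instantaneous amplitude combines a small
    sensor-noise floor with a component proportional to speed (in
    quadrature), so the muscle is silent at rest and the rectified average
    rises sharply at movement onset.
    """
    speed_sig, t_sig = _kin_speed_at_sig_rate(kin, params.sig_rate)
    amp = np.sqrt(_EMG_NOISE_FLOOR**2 + (_EMG_GAIN * speed_sig) ** 2)
    data = amp * seed_stream.standard_normal(speed_sig.size)
    return SignalTrace(data=data, rate=params.sig_rate, t0=float(t_sig[0]), name="emg")


def epoch_frame_times(
    window: tuple[float, float] = (-4.0, 8.0),
    sig_rate: float = 1200.0,
    window_ms: float = 100.0,
    hop_ms: float = 10.0,
) -> np.ndarray:
    """Window-center frame times of an epoch spectrogram, relative to onset."""
    n_win = int(round(window_ms * 1e-3 * sig_rate))
    hop = int(round(hop_ms * 1e-3 * sig_rate))
    n_samples = int(round((window[1] - window[0]) * sig_rate))
    n_frames = (n_samples - n_win) // hop + 1
    return window[0] + (np.arange(n_frames) * hop + n_win / 2.0) / sig_rate


def _hamming_sq_kernel(window_ms: float, hop_ms: float) -> np.ndarray:
    n = max(int(round(window_ms / hop_ms)) + 1, 1)
    w = get_window("hamming", n) ** 2
    return w / w.sum()


def _template_for_plan(
    plan: _TrialPlan,
    params: SessionParams,
    fmax: float = 200.0,
    window: tuple[float, float] = (-4.0, 8.0),
    window_ms: float = 100.0,
    hop_ms: float = 10.0,
    baseline_window: tuple[float, float] = (-2.0, -1.0),
) -> NormalizedSpectrogram:
    """Expected normalized spectrogram for one trial (the ground truth).

    Built from the same PSD model the generator samples from: expected power
    per cell is background + beta * envelope^2 + ers_gain * speed * gamma
    level, with the speed and envelope time courses smeared by the squared
    analysis window to mimic the spectrogram's temporal smoothing.  The
    result is normalized exactly like the measured spectrograms, so it is
    the noiseless target that conventional and warped averages are judged
    against.  Band-edge spectral leakage of the analysis window is not
    modeled.
    """
    ft = epoch_frame_times(window, params.sig_rate, window_ms, hop_ms)
    t_abs = plan.onset + ft
    speed = plan.speed(t_abs)
    gate = _smooth_gate(speed > ONSET_SPEED_THRESHOLD, 1000.0 / hop_ms)
    env2 = (1.0 - (1.0 - params.erd_depth) * gate) ** 2
    kernel = _hamming_sq_kernel(window_ms, hop_ms)
    env2 = np.convolve(env2, kernel, mode="same")
    speed_sm = np.convolve(speed, kernel, mode="same")

    freqs = np.arange(0.0, fmax + 0.5, 1.0)
    p_bg = _psd_background(freqs)
    in_beta = (freqs >= params.beta_band[0]) & (freqs <= params.beta_band[1])
    in_gamma = (freqs >= params.gamma_band[0]) & (freqs <= params.gamma_band[1])
    p_beta = np.where(in_beta, _band_psd_level(params.beta_band, _BETA_POWER_RATIO), 0.0)
    p_gamma = np.where(in_gamma, _band_psd_level(params.gamma_band, 1.0), 0.0)

    power = (
        p_bg[np.newaxis, :]
        + p_beta[np.newaxis, :] * env2[:, np.newaxis]
        + p_gamma[np.newaxis, :] * (params.ers_gain * speed_sm)[:, np.newaxis]
    )
    if params.line_noise_hz is not None and params.line_noise_hz <= fmax:
        # coarse: spread the tone's power over roughly the window's ENBW
        k = int(round(params.line_noise_hz))
        power[:, k] += 2.0 * p_bg.sum() / 1.36
    b_mask = (ft >= baseline_window[0]) & (ft < baseline_window[1])
    b = power[b_mask].mean(axis=0)
    values = 100.0 * (power - b) / b
    return NormalizedSpectrogram(
        frame_times=ft, freqs=freqs, values=values,
        baseline=b, baseline_window=baseline_window,
    )


def generate_session(
    params: SessionParams,
    with_templates: bool = True,
    template_fmax: float = 200.0,
) -> SyntheticSession:
    """Generate a full seeded session of kinematics + ECoG + EMG trials.

    Bit-identical for identical ``params`` (including the seed).  Each
    trial's ground-truth template lives on the epoch frame grid relative to
    its own true onset, cropped at ``template_fmax``.
    """
    trials = []
    for i in range(params.n_trials):
        kin_rng, ecog_rng, emg_rng = _trial_rngs(params, i)
        plan = _draw_plan(params, kin_rng)
        kin = _plan_to_trace(plan, params)
        ecog = gen_ecog_from_velocity(kin, params, ecog_rng)
        emg = gen_emg_from_velocity(kin, params, emg_rng)
        template = (
            _template_for_plan(plan, params, fmax=template_fmax)
            if with_templates
            else None
        )
        trials.append(
            SyntheticTrial(
                trial_id=i,
                kinematics=kin,
                ecog=ecog,
                emg=emg,
                cue_time=plan.cue_time,
                true_onset=plan.onset,
                true_phase_boundaries=(
                    plan.reach_end,
                    plan.retrieve_start,
                    plan.retrieve_end,
                ),
                ground_truth_template=template,
                plan=plan,
            )
        )
    return SyntheticSession(params=params, trials=trials)
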