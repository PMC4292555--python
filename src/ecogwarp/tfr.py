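"""Time-frequency analysis: Hamming-window spectrograms, ERD/ERS baseline
normalization and band-power extraction.

The spectrogram convention follows common practice for movement-related
ECoG: 100 ms Hamming windows advanced in 10 ms hops, each segment
zero-padded so frequency bins fall on an exact 1 Hz grid, power as squared
magnitude.  Event-related changes are expressed per frequency as percent
change relative to the mean power of a pre-movement baseline interval
(conventionally -2..-1 s before onset), so a desynchronization (ERD) is
negative and a synchronization (ERS) positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft
from scipy.signal import get_window

from .containers import SignalTrace

__all__ = [
    "Spectrogram",
    "NormalizedSpectrogram",
    "compute_spectrogram",
    "baseline_normalize",
    "band_power",
]


@dataclass
class Spectrogram:
    """Time-frequency power matrix.

    ``power`` has shape (n_frames, n_freqs); each row is the power spectrum
    of one windowed segment, each column the time course of power at one
    frequency.  ``frame_times`` are window-center times in seconds relative
    to movement onset; ``freqs`` are bin centers in Hz on a uniform grid.
    """

    frame_times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.frame_times.size, self.freqs.size):
            raise ValueError("power must be (n_frames, n_freqs)")

    @property
    def values(self) -> np.ndarray:  # uniform cell access with NormalizedSpectrogram
        return self.power

    @property
    def hop(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass
class NormalizedSpectrogram:
    """Percent change from baseline, same axes as :class:`Spectrogram`.

    ``values`` is 100 * (P - B) / B per cell, bounded below by -100 because
    power is non-negative.  ``baseline`` stores B(f) so the normalization is
    invertible.
    """

    frame_times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    baseline: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.frame_times.size, self.freqs.size):
            raise ValueError("values must be (n_frames, n_freqs)")

    def to_power(self) -> Spectrogram:
        """Invert the percent-change normalization (requires ``baseline``)."""
        if self.baseline is None:
            raise ValueError("baseline was not stored; cannot invert")
        p = (self.values / 100.0 + 1.0) * self.baseline[np.newaxis, :]
        return Spectrogram(self.frame_times, self.freqs, p)


def compute_spectrogram(
    signal: SignalTrace,
    window_ms: float = 100.0,
    hop_ms: float = 10.0,
    freq_resolution_hz: float = 1.0,
    fmax: float | None = None,
) -> Spectrogram:
    """Short-time Fourier power spectrogram with a Hamming window.

    Each ``window_ms`` segment is multiplied by a Hamming window and
    zero-padded to ``rate / freq_resolution_hz`` samples so bins land on an
    exact ``freq_resolution_hz`` grid (spectral interpolation; the intrinsic
    resolution remains that of the window).  Only windows fully inside the
    signal are used, and each frame is stamped at its window center, so a
    12 s epoch at 1200 Hz with the defaults yields 1191 frames of 601 bins
    (0-600 Hz).  No window-gain compensation is applied: all downstream
    comparisons are ratios to baseline, in which the gain cancels.

    Parameters
    ----------
    fmax
        If given, the frequency axis is cropped to ``freqs <= fmax`` (a
        convenience for band-limited analyses; 200 Hz comfortably covers the
        beta and gamma ranges of interest).
    """
    n_win = int(round(window_ms * 1e-3 * signal.rate))
    hop = int(round(hop_ms * 1e-3 * signal.rate))
    n_fft = int(round(signal.rate / freq_resolution_hz))
    if n_win < 2 or hop < 1:
        raise ValueError("window/hop too short for this sampling rate")
    if n_fft < n_win:
        raise ValueError("freq_resolution_hz too coarse: FFT shorter than window")
    if len(signal) < n_win:
        raise ValueError("signal shorter than one analysis window")

    frames = sliding_window_view(signal.data, n_win)[::hop]
    win = get_window("hamming", n_win)
    spec = rfft(frames * win, n=n_fft, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.arange(power.shape[1]) * freq_resolution_hz
    starts = np.arange(frames.shape[0]) * hop
    frame_times = signal.t0 + (starts + n_win / 2.0) / signal.rate
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs, power = freqs[keep], power[:, keep]
    return Spectrogram(frame_times=frame_times, freqs=freqs, power=power)


def baseline_normalize(
    spec: Spectrogram, baseline_window: tuple[float, float] = (-2.0, -1.0)
) -> NormalizedSpectrogram:
    """Express power as percent change from a pre-movement baseline.

    B(f) is the mean of P(f, t) over frames with
    ``baseline_window[0] <= t < baseline_window[1]``; the output cell is
    ``100 * (P - B) / B``.

    Raises
    ------
    ValueError
        If the window contains no frames, or if B(f) vanishes at some
        frequency (the offending frequency is named).
    """
    lo, hi = baseline_window
    mask = (spec.frame_times >= lo) & (spec.frame_times < hi)
    if not mask.any():
        raise ValueError("baseline window contains no spectrogram frames")
    b = spec.power[mask].mean(axis=0)
    zero = np.flatnonzero(b <= 0)
    if zero.size:
        raise ValueError(
            f"degenerate baseline: zero power at {spec.freqs[zero[0]]:g} Hz"
        )
    values = 100.0 * (spec.power - b) / b
    return NormalizedSpectrogram(
        frame_times=spec.frame_times.copy(),
        freqs=spec.freqs.copy(),
        values=values,
        baseline=b,
        baseline_window=(lo, hi),
    )


def band_power(
    spec: Spectrogram | NormalizedSpectrogram, band: tuple[float, float]
) -> np.ndarray:
    """Per-frame mean over frequency bins whose center lies in ``band``.

    Inclusive at both edges.  Works on raw power and on normalized
    (percent-change) spectrograms alike; canonical bands are beta 12-30 Hz
    and gamma 65-140 Hz.
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return spec.values[:, mask].mean(axis=1)
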