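"""Shared in-memory containers for regularly sampled signals and epoched trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalTrace", "Trial"]


@dataclass
class SignalTrace:
    """A regularly sampled single-channel signal.

    Parameters
    ----------
    data
        Sample values, 1-D.
    rate
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds.  For epoched traces this is
        expressed relative to movement onset (t = 0), e.g. ``t0 = -4.0``.
    name
        Optional channel label (e.g. ``"ecog"``, ``"emg_flexor"``).
    """

    data: np.ndarray
    rate: float
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("SignalTrace.data must be one-dimensional")
        if not (self.rate > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.data.size) / self.rate

    @property
    def duration(self) -> float:
        return self.data.size / self.rate

    def __len__(self) -> int:
        return self.data.size


@dataclass
class Trial:
    """One epoch of synchronized signals and kinematics around movement onset.

    All member traces carry times relative to the detected movement onset
    (t = 0); the epoch window is fixed, conventionally [-4 s, +8 s).
    """

    trial_id: int
    onset: float  # absolute onset time in the source recording, seconds
    ecog: SignalTrace
    kinematics: "object"  # KinematicTrace; kept loose to avoid circular import
    emg: SignalTrace | None = None
    window: tuple[float, float] = (-4.0, 8.0)
    extras: dict = field(default_factory=dict)
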