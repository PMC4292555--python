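"""Run configuration: analysis parameters, channel roles and validation.

Defaults are the standard conventions of the movement-ECoG analysis this
package implements: 100 ms Hamming window / 10 ms hop / 1 Hz bins,
baseline -2..-1 s, onset threshold 0.5 cm/s, epoch -4..+8 s, beta 12-30 Hz,
gamma 65-140 Hz, gamma-derived warping band 65-90 Hz.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, fields, replace
from pathlib import Path

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # spectrogram
    window_ms: float = 100.0
    hop_ms: float = 10.0
    freq_resolution_hz: float = 1.0
    fmax: float = 200.0
    # epoching / kinematics
    epoch_window: tuple[float, float] = (-4.0, 8.0)
    baseline_window: tuple[float, float] = (-2.0, -1.0)
    movement_window: tuple[float, float] = (0.0, 1.0)
    onset_threshold: float = 0.5  # cm/s
    smooth_window: int = 5  # samples of velocity moving average
    # bands
    beta_band: tuple[float, float] = (12.0, 30.0)
    gamma_band: tuple[float, float] = (65.0, 140.0)
    gamma_warp_band: tuple[float, float] = (65.0, 90.0)
    # alignment
    reference_strategy: str = "medoid"  # medoid | index
    reference_index: int = 0
    warp_on: str = "vx"  # vx | speed
    paired_test: bool = False
    # io / channel roles
    ecog_channels: tuple[str, str] | None = None  # bipolar pair
    emg_channels: tuple[str, ...] = ()
    kinematics_file: str | None = None
    seed: int = 0

    def validate(self, sig_rate: float | None = None) -> None:
        if self.window_ms <= 0 or self.hop_ms <= 0 or self.hop_ms > self.window_ms:
            raise ConfigError("need 0 < hop_ms <= window_ms")
        if self.onset_threshold <= 0:
            raise ConfigError("onset_threshold must be positive (cm/s)")
        if self.smooth_window < 1:
            raise ConfigError("smooth_window must be >= 1")
        for name in ("epoch_window", "baseline_window", "movement_window",
                     "beta_band", "gamma_band", "gamma_warp_band"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ConfigError(f"{name} must be an increasing (lo, hi) pair")
        lo, hi = self.epoch_window
        for name in ("baseline_window", "movement_window"):
            wlo, whi = getattr(self, name)
            if wlo < lo or whi > hi:
                raise ConfigError(f"{name} must lie within the epoch window")
        if self.reference_strategy not in ("medoid", "index"):
            raise ConfigError("reference_strategy must be 'medoid' or 'index'")
        if self.warp_on not in ("vx", "speed"):
            raise ConfigError("warp_on must be 'vx' or 'speed'")
        if sig_rate is not None:
            nyq = sig_rate / 2.0
            for name in ("beta_band", "gamma_band", "gamma_warp_band"):
                if getattr(self, name)[1] >= nyq:
                    raise ConfigError(f"{name} exceeds the Nyquist frequency {nyq} Hz")
            if self.fmax >= nyq + 1e-9:
                raise ConfigError("fmax exceeds the Nyquist frequency")

    # -- serialization: flat key = value text, round-trip safe ----------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def to_file(self, path) -> None:
        lines = [f"{k} = {v!r}" for k, v in sorted(self.to_dict().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in {f.name for f in fields(cls)}:
                raise ConfigError(f"unknown configuration key {key!r}")
            value = ast.literal_eval(raw.strip())
            if isinstance(value, list):
                value = tuple(value)
            cfg = replace(cfg, **{key: value})
        if overrides:
            cfg = replace(cfg, **overrides)
        cfg.validate()
        return cfg
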