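"""Readers and writers: delimited-text kinematics and signals, EDF signal
ingestion, JSON sidecars for ground truth, registration paths and reports.

Delimited text is the canonical interchange format here (kinematics as
``time_s,x_cm,y_cm,z_cm``; signals as ``time_s,value``); EDF recordings can
be read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SignalTrace
from .kinematics import KinematicTrace
from .warp import RegistrationPath

__all__ = [
    "read_kinematics",
    "write_kinematics",
    "read_signal_text",
    "write_signal_text",
    "read_edf_channels",
    "bipolar_derivation",
    "write_session",
    "read_session",
    "save_path_json",
    "load_path_json",
    "save_report",
]

KIN_COLUMNS = ["time_s", "x_cm", "y_cm", "z_cm"]


def write_kinematics(path, trace: KinematicTrace) -> None:
    df = pd.DataFrame(
        np.column_stack([trace.timestamps, trace.position]), columns=KIN_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_kinematics(path) -> KinematicTrace:
    df = pd.read_csv(path)
    missing = [c for c in KIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinematics file lacks columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("kinematics timestamps must be strictly increasing")
    return KinematicTrace(timestamps=t, position=df[KIN_COLUMNS[1:]].to_numpy(float))


def write_signal_text(path, sig: SignalTrace) -> None:
    df = pd.DataFrame({"time_s": sig.times, "value": sig.data})
    df.to_csv(path, index=False, float_format="%.8g")


def read_signal_text(path, name: str = "") -> SignalTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t)))
    return SignalTrace(
        data=df["value"].to_numpy(dtype=float), rate=round(rate, 6), t0=float(t[0]),
        name=name or Path(str(path)).stem,
    )


def read_edf_channels(path, channels: list[str]) -> dict[str, SignalTrace]:
    """Read named channels from an EDF recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(path, include=channels, preload=True, verbose="error")
    out = {}
    for ch in channels:
        data = raw.get_data(picks=[ch])[0]
        out[ch] = SignalTrace(data=data, rate=float(raw.info["sfreq"]), name=ch)
    return out


def bipolar_derivation(a: SignalTrace, b: SignalTrace) -> SignalTrace:
    """Contact difference of two ECoG channels (common-mode rejection)."""
    if len(a) != len(b) or a.rate != b.rate:
        raise ValueError("bipolar pair must share length and rate")
    return SignalTrace(a.data - b.data, a.rate, t0=a.t0, name=f"{a.name}-{b.name}")


# --------------------------------------------------------------------------
# session directory layout: trial_%03d_{kin,ecog,emg}.csv + session.json

def write_session(directory, session) -> None:
    """Write a synthetic session as delimited text plus a ground-truth sidecar.

    The JSON sidecar stores the generator parameters, cue times, true onsets
    and phase boundaries; the (large) ground-truth template matrices are not
    serialized — regenerate the session to recover them.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"params": _params_dict(session.params), "trials": []}
    for tr in session.trials:
        stem = f"trial_{tr.trial_id:03d}"
        write_kinematics(directory / f"{stem}_kin.csv", tr.kinematics)
        write_signal_text(directory / f"{stem}_ecog.csv", tr.ecog)
        write_signal_text(directory / f"{stem}_emg.csv", tr.emg)
        meta["trials"].append(
            {
                "trial_id": tr.trial_id,
                "cue_time": tr.cue_time,
                "true_onset": tr.true_onset,
                "true_phase_boundaries": list(tr.true_phase_boundaries),
            }
        )
    (directory / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _params_dict(params) -> dict:
    from dataclasses import asdict

    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


class SessionTrialFiles:
    """Lazy handle onto one trial of an on-disk session."""

    def __init__(self, directory: Path, meta: dict):
        self._dir = directory
        self.trial_id = int(meta["trial_id"])
        self.cue_time = float(meta["cue_time"])
        self.true_onset = float(meta.get("true_onset", np.nan))
        self.true_phase_boundaries = tuple(meta.get("true_phase_boundaries", ()))
        stem = f"trial_{self.trial_id:03d}"
        self.kinematics = read_kinematics(directory / f"{stem}_kin.csv")
        self.ecog = read_signal_text(directory / f"{stem}_ecog.csv", name="ecog")
        emg_path = directory / f"{stem}_emg.csv"
        self.emg = read_signal_text(emg_path, name="emg") if emg_path.exists() else None


def read_session(directory):
    """Load a session directory written by :func:`write_session`."""
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    return meta["params"], [SessionTrialFiles(directory, m) for m in meta["trials"]]


# --------------------------------------------------------------------------

def save_path_json(path, reg: RegistrationPath, meta: dict | None = None) -> None:
    obj = {
        "pairs": reg.pairs.tolist(),
        "total_cost": reg.total_cost,
        "n_ref": reg.n_ref,
        "n_query": reg.n_query,
        "normalized_cost": reg.normalized_cost,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(obj, sort_keys=True))


def load_path_json(path) -> RegistrationPath:
    obj = json.loads(Path(path).read_text())
    return RegistrationPath(
        pairs=np.asarray(obj["pairs"], dtype=np.intp),
        total_cost=float(obj["total_cost"]),
        n_ref=int(obj["n_ref"]),
        n_query=int(obj["n_query"]),
        meta=obj.get("meta", {}),
    )


def save_report(path, report: dict) -> None:
    """Canonical (sorted, fixed-format) JSON so identical runs are byte-identical."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
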