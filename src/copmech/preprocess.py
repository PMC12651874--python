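"""Force-plate trial I/O, center-of-pressure derivation, trimming and filtering.

A force plate reports three force components (Fx, Fy, Fz, in newtons) and
three moment components (Mx, My, Mz, in newton-metres) about its origin.
With the origin on the plate surface, the point of application of the
vertical ground reaction force — the center of pressure (COP) — follows
from moment balance:

    COP_ML = -My / Fz        (x axis, mediolateral)
    COP_AP =  Mx / Fz        (y axis, anterior-posterior)

COP is expressed in millimetres throughout the package; forces and moments
stay in SI units. Samples where the plate is unloaded (Fz below a validity
threshold) are masked rather than producing spurious COP values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ForcePlateTrial",
    "COPTrajectory",
    "FilterSpec",
    "read_trial",
    "write_trial",
    "compute_cop",
    "trim",
    "lowpass",
    "preprocess_trial",
]

#: Columns of the trial CSV dialect, in order. SI units (s, N, N·m).
TRIAL_COLUMNS = ("time", "Fx", "Fy", "Fz", "Mx", "My", "Mz")

#: Default vertical-force validity threshold (N).
DEFAULT_FZ_THRESHOLD = 50.0

_TIME_UNIFORMITY_TOL = 1e-9  # s


@dataclass
class ForcePlateTrial:
    """One recorded (or simulated) trial of 6-channel force-plate data."""

    fs: float
    t: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    Mx: np.ndarray
    My: np.ndarray
    Mz: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        arrays = [self.t, self.Fx, self.Fy, self.Fz, self.Mx, self.My, self.Mz]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise ValueError("all trial channels must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time vector must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > _TIME_UNIFORMITY_TOL + 1.0 / self.fs * 1e-6:
                raise ValueError("time vector is not uniform at the stated sampling rate")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "Fx": self.Fx, "Fy": self.Fy, "Fz": self.Fz,
            "Mx": self.Mx, "My": self.My, "Mz": self.Mz,
        }


@dataclass
class COPTrajectory:
    """Center-of-pressure series in mm: ``ml`` (x) and ``ap`` (y)."""

    ml: np.ndarray
    ap: np.ndarray
    fs: float
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.ml) == len(self.ap) == len(self.valid_mask)):
            raise ValueError("ml, ap and valid_mask must have equal length")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.ml)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        offset = float(self.meta.get("t0", 0.0))
        return offset + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass specification."""

    order: int = 4
    cutoff: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def read_trial(path: str | os.PathLike, meta: dict | None = None) -> ForcePlateTrial:
    """Read a trial from the package CSV dialect (``time,Fx,Fy,Fz,Mx,My,Mz``).

    Metadata (subject, group, session, test type, events) comes from the
    cohort sidecar table and is passed in through ``meta``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    bad = df[list(TRIAL_COLUMNS)].isna()
    if bad.any().any():
        rows = (np.nonzero(bad.any(axis=1).to_numpy())[0] + 2)[:10]  # 1-based + header
        raise ValueError(f"{path}: malformed rows at lines {rows.tolist()}")
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: trial must contain at least two samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > _TIME_UNIFORMITY_TOL + abs(dt[0]) * 1e-6:
        raise ValueError(f"{path}: non-uniform sampling interval")
    fs = 1.0 / dt[0]
    return ForcePlateTrial(
        fs=float(round(fs, 6)),
        t=t,
        Fx=df["Fx"].to_numpy(float),
        Fy=df["Fy"].to_numpy(float),
        Fz=df["Fz"].to_numpy(float),
        Mx=df["Mx"].to_numpy(float),
        My=df["My"].to_numpy(float),
        Mz=df["Mz"].to_numpy(float),
        meta=dict(meta or {}),
    )


def write_trial(trial: ForcePlateTrial, path: str | os.PathLike) -> None:
    """Write a trial in the CSV dialect read by :func:`read_trial`."""
    df = pd.DataFrame(
        {
            "time": trial.t,
            "Fx": trial.Fx, "Fy": trial.Fy, "Fz": trial.Fz,
            "Mx": trial.Mx, "My": trial.My, "Mz": trial.Mz,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def compute_cop(
    trial: ForcePlateTrial,
    fz_threshold: float = DEFAULT_FZ_THRESHOLD,
    z_offset: float = 0.0,
) -> COPTrajectory:
    """Derive the COP trajectory (mm) from plate moments and vertical force.

    ``z_offset`` (m) shifts the moment reference plane for plates that report
    moments about an internal sensor plane rather than the top surface:
    COP_ML = (-My - Fx*z0)/Fz, COP_AP = (Mx - Fy*z0)/Fz.
    """
    if fz_threshold <= 0:
        raise ValueError("fz_threshold must be positive")
    valid = trial.Fz >= fz_threshold
    if not np.any(valid):
        raise ValueError("no loaded samples: Fz never reaches the validity threshold")
    with np.errstate(divide="ignore", invalid="ignore"):
        ml_m = (-trial.My - trial.Fx * z_offset) / trial.Fz
        ap_m = (trial.Mx - trial.Fy * z_offset) / trial.Fz
    ml = np.where(valid, ml_m, 0.0) * 1000.0
    ap = np.where(valid, ap_m, 0.0) * 1000.0
    return COPTrajectory(ml=ml, ap=ap, fs=trial.fs, valid_mask=valid, meta=dict(trial.meta))


def trim(cop: COPTrajectory, head: float, tail: float) -> COPTrajectory:
    """Drop ``head`` and ``tail`` seconds of transient from either end."""
    if head < 0 or tail < 0:
        raise ValueError("trim lengths must be non-negative")
    n_head = int(round(head * cop.fs))
    n_tail = int(round(tail * cop.fs))
    if n_head + n_tail >= cop.n_samples:
        raise ValueError(
            f"cannot trim {head}+{tail} s from a {cop.duration:.3f} s trajectory"
        )
    sl = slice(n_head, cop.n_samples - n_tail)
    meta = dict(cop.meta)
    meta["t0"] = float(meta.get("t0", 0.0)) + n_head / cop.fs
    return COPTrajectory(
        ml=cop.ml[sl].copy(), ap=cop.ap[sl].copy(), fs=cop.fs,
        valid_mask=cop.valid_mask[sl].copy(), meta=meta,
    )


def lowpass(cop: COPTrajectory, spec: FilterSpec = FilterSpec()) -> COPTrajectory:
    """Zero-phase (forward-backward) Butterworth low-pass, per axis."""
    nyq = cop.fs / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyq} Hz")
    b, a = signal.butter(spec.order, spec.cutoff / nyq)
    ml = signal.filtfilt(b, a, cop.ml)
    ap = signal.filtfilt(b, a, cop.ap)
    return COPTrajectory(ml=ml, ap=ap, fs=cop.fs, valid_mask=cop.valid_mask.copy(),
                         meta=dict(cop.meta))


def preprocess_trial(
    trial: ForcePlateTrial,
    fz_threshold: float = DEFAULT_FZ_THRESHOLD,
    filter_spec: FilterSpec = FilterSpec(),
    head: float | None = None,
    tail: float | None = None,
) -> COPTrajectory:
    """Full chain: COP derivation → transient trim → zero-phase low-pass.

    Default trims depend on the test type: 2 s head and tail for quiet
    standing; for gait-initiation trials only the pre-cue head is trimmed,
    leaving 1 s of baseline before the cue, and no tail is removed.
    """
    cop = compute_cop(trial, fz_threshold=fz_threshold)
    test_type = trial.meta.get("test_type", "standing")
    if head is None or tail is None:
        if test_type == "gait_initiation":
            cue = float(trial.meta.get("events", {}).get("cue_time", 3.0))
            head = max(cue - 1.0, 0.0) if head is None else head
            tail = 0.0 if tail is None else tail
        else:
            head = 2.0 if head is None else head
            tail = 2.0 if tail is None else tail
    cop = trim(cop, head, tail)
    return lowpass(cop, filter_spec)


def write_cop(cop: COPTrajectory, path: str | os.PathLike) -> None:
    """Write a preprocessed COP series as ``time,cop_ml_mm,cop_ap_mm,valid``."""
    pd.DataFrame(
        {
            "time": cop.t,
            "cop_ml_mm": cop.ml,
            "cop_ap_mm": cop.ap,
            "valid": cop.valid_mask.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.9g")


def restrict_valid(cop: COPTrajectory) -> COPTrajectory:
    """Return the longest prefix-contiguous view of valid samples.

    Feature computations require a contiguous valid segment; trials whose
    plate is loaded throughout pass through unchanged.
    """
    if np.all(cop.valid_mask):
        return cop
    idx = np.nonzero(cop.valid_mask)[0]
    if idx.size == 0:
        raise ValueError("no loaded samples")
    # longest contiguous run of valid samples
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    lengths = ends - starts
    j = int(np.argmax(lengths))
    sl = slice(idx[starts[j]], idx[ends[j]] + 1)
    meta = dict(cop.meta)
    meta["t0"] = float(meta.get("t0", 0.0)) + sl.start / cop.fs
    return COPTrajectory(ml=cop.ml[sl], ap=cop.ap[sl], fs=cop.fs,
                         valid_mask=cop.valid_mask[sl], meta=meta)
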