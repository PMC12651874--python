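"""Synthetic force-plate cohort generator.

The study design this package targets — quiet-standing and gait-initiation
trials from Parkinson's disease (PD) patients and healthy controls — rests
on recordings that are not publicly deposited, so a seeded simulator stands
in for them. It emulates the statistical structure the analysis relies on,
not the biomechanics of a specific cohort:

* **Quiet standing.** Latent COP sway follows a 2-D mean-reverting
  (Ornstein-Uhlenbeck) diffusion per axis,

      c[t+1] = c[t] + theta * (mu - c[t]) * dt + sigma * sqrt(dt) * eps,

  chosen because its stationary standard deviation has the closed form
  sigma / sqrt(2*theta), giving downstream feature extraction an analytic
  oracle. PD presets have larger mediolateral diffusion (higher RMS sway)
  and larger anterior-posterior diffusion (longer AP path length) than
  healthy presets.

* **Gait initiation.** The COP holds a baseline for ``cue_time`` seconds,
  then executes a single-step anticipatory postural adjustment (APA):
  a cosine-ramp excursion toward the swing limb and posteriorly (loading),
  followed by a reversal past baseline toward the stance side (unloading).
  PD presets scale the APA amplitude down. Ground-truth phase boundaries
  travel in trial metadata for segmentation tests.

* **Force/moment channels.** Channels are mechanically consistent with the
  latent COP: Fz = mass*g with small multiplicative noise, Mx = COP_AP*Fz,
  My = -COP_ML*Fz (COP in metres inside the identity), and Fx/Fy are small
  zero-mean noise. Recomputing COP from the channels recovers the latent
  trajectory exactly wherever the plate is loaded.

* **Intervention.** The exercise effect is a convex shift of a PD
  subject's generative parameters toward the healthy preset by a factor
  ``lam`` (default 0.6) applied to the post session.

Identical (config, seed) always yields identical trials.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ForcePlateTrial, write_trial

__all__ = [
    "SwayParams",
    "GaitTemplateParams",
    "SubjectProfile",
    "CohortConfig",
    "CohortTruth",
    "healthy_sway",
    "pd_sway",
    "healthy_gait",
    "pd_gait",
    "simulate_standing_trial",
    "simulate_gait_initiation_trial",
    "simulate_cohort",
    "write_cohort",
]

G = 9.81  # m/s^2

GROUPS = ("healthy", "pd_control", "pd_tpei")
SESSIONS = ("pre", "post", "single")


@dataclass(frozen=True)
class SwayParams:
    """Mean-reverting sway diffusion parameters (per-axis).

    theta_*: mean-reversion rate (1/s); sigma_*: diffusion scale (mm/sqrt(s));
    cop_offset_*: equilibrium COP position on the plate (mm).
    """

    theta_ml: float = 1.0
    theta_ap: float = 1.0
    sigma_ml: float = 1.0
    sigma_ap: float = 1.0
    cop_offset_ml: float = 0.0
    cop_offset_ap: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_ml <= 0 or self.theta_ap <= 0:
            raise ValueError("mean-reversion rates must be positive")
        if self.sigma_ml < 0 or self.sigma_ap < 0:
            raise ValueError("diffusion scales must be non-negative")


@dataclass(frozen=True)
class GaitTemplateParams:
    """Single-step APA template for gait initiation.

    ``apa_ml_amplitude`` is signed toward the swing limb;
    ``apa_ap_amplitude`` is the posterior excursion (negative = posterior).
    """

    cue_time: float = 3.0
    apa_ml_amplitude: float = 30.0
    apa_ap_amplitude: float = -25.0
    loading_duration: float = 0.5
    unloading_duration: float = 0.6
    template_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.loading_duration <= 0 or self.unloading_duration <= 0:
            raise ValueError("phase durations must be positive")
        if self.cue_time < 1:
            raise ValueError("cue_time must be at least 1 s")
        if self.template_noise_sd < 0:
            raise ValueError("template noise SD must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    session: str
    age: float
    sex: str
    bmi: float
    mass: float
    sway: SwayParams = SwayParams()
    gait: GaitTemplateParams = GaitTemplateParams()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.group == "healthy" and self.session != "single":
            raise ValueError("healthy subjects carry a single session")
        if self.group != "healthy" and self.session == "single":
            raise ValueError("PD subjects carry pre/post sessions")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


# ---------------------------------------------------------------------------
# Presets: the group-level contrasts the cohort is built around.
# PD > healthy in ML sway diffusion (RMS-SML) and AP diffusion (PL-SAP);
# PD APA amplitude scaled to 0.6x healthy (LDisp-Gait reduced).

def healthy_sway() -> SwayParams:
    return SwayParams(theta_ml=1.0, theta_ap=1.0, sigma_ml=1.0, sigma_ap=1.0)


def pd_sway() -> SwayParams:
    return SwayParams(theta_ml=1.0, theta_ap=1.0, sigma_ml=3.0, sigma_ap=2.0)


def healthy_gait() -> GaitTemplateParams:
    return GaitTemplateParams()


def pd_gait() -> GaitTemplateParams:
    h = healthy_gait()
    return dataclasses.replace(
        h, apa_ml_amplitude=0.6 * h.apa_ml_amplitude,
        apa_ap_amplitude=0.6 * h.apa_ap_amplitude,
    )


def blend_sway(a: SwayParams, b: SwayParams, lam: float) -> SwayParams:
    """Convex combination ``a + lam*(b - a)`` field-wise."""
    kw = {
        f.name: (1 - lam) * getattr(a, f.name) + lam * getattr(b, f.name)
        for f in dataclasses.fields(SwayParams)
    }
    return SwayParams(**kw)


def blend_gait(a: GaitTemplateParams, b: GaitTemplateParams, lam: float) -> GaitTemplateParams:
    kw = {
        f.name: (1 - lam) * getattr(a, f.name) + lam * getattr(b, f.name)
        for f in dataclasses.fields(GaitTemplateParams)
    }
    return GaitTemplateParams(**kw)


# ---------------------------------------------------------------------------
# Trial generation

def _ou_path(n: int, dt: float, theta: float, sigma: float, mu: float,
             rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama discretization of the OU diffusion, started at mu.

    The recursion d[i] = (1 - theta*dt) * d[i-1] + sigma*sqrt(dt)*eps[i]
    on the deviation d = c - mu is a first-order AR filter, evaluated
    with :func:`scipy.signal.lfilter` for speed.
    """
    from scipy.signal import lfilter

    eps = rng.standard_normal(n)
    step = sigma * np.sqrt(dt)
    decay = 1.0 - theta * dt
    dev = lfilter([step], [1.0, -decay], eps)
    return mu + dev


def _channels_from_cop(
    cop_ml_mm: np.ndarray,
    cop_ap_mm: np.ndarray,
    mass: float,
    fs: float,
    rng: np.random.Generator,
    fz_noise_frac: float = 0.005,
    fxy_noise_sd: float = 0.5,
    com_cutoff: float = 0.5,
    com_height: float = 1.0,
) -> dict[str, np.ndarray]:
    """Force/moment channels mechanically consistent with a latent COP.

    Shear follows the small-angle inverted-pendulum relation
    F_h = m*g*(x_COM - x_COP)/h, with the COM taken as the ``com_cutoff``
    Hz low-pass of the COP (the COM tracks only the slow component of the
    COP), plus a ``fxy_noise_sd`` sensor-noise floor. Fz carries small
    multiplicative noise about body weight; Mx/My satisfy the COP moment
    identity exactly; Mz is free-moment sensor noise.
    """
    from scipy.signal import butter, filtfilt

    n = len(cop_ml_mm)
    weight = mass * G
    Fz = weight * (1.0 + fz_noise_frac * rng.standard_normal(n))
    Fz = np.maximum(Fz, 0.5 * weight)  # the subject never unloads the plate
    if 0 < com_cutoff < fs / 2 and n > 15:
        b, a = butter(2, com_cutoff / (fs / 2))
        com_ml = filtfilt(b, a, cop_ml_mm)
        com_ap = filtfilt(b, a, cop_ap_mm)
    else:
        com_ml, com_ap = cop_ml_mm, cop_ap_mm
    Fx = weight * (com_ml - cop_ml_mm) / 1000.0 / com_height \
        + fxy_noise_sd * rng.standard_normal(n)
    Fy = weight * (com_ap - cop_ap_mm) / 1000.0 / com_height \
        + fxy_noise_sd * rng.standard_normal(n)
    Mx = (cop_ap_mm / 1000.0) * Fz
    My = -(cop_ml_mm / 1000.0) * Fz
    Mz = 0.1 * rng.standard_normal(n)
    return {"Fx": Fx, "Fy": Fy, "Fz": Fz, "Mx": Mx, "My": My, "Mz": Mz}


def simulate_standing_trial(
    profile: SubjectProfile,
    duration: float = 30.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> ForcePlateTrial:
    """Simulate a quiet-standing trial of ``duration`` seconds at ``fs`` Hz."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    p = profile.sway
    ml = _ou_path(n, dt, p.theta_ml, p.sigma_ml, p.cop_offset_ml, rng)
    ap = _ou_path(n, dt, p.theta_ap, p.sigma_ap, p.cop_offset_ap, rng)
    ch = _channels_from_cop(ml, ap, profile.mass, fs, rng)
    t = np.arange(n) * dt
    meta = {
        "subject_id": profile.subject_id,
        "group": profile.group,
        "session": profile.session,
        "test_type": "standing",
        "events": {},
    }
    return ForcePlateTrial(fs=fs, t=t, **ch, meta=meta)


def _cosine_ramp(a: float, b: float, n: int) -> np.ndarray:
    """Smooth monotone ramp from a to b over n samples (endpoints included)."""
    s = np.linspace(0.0, 1.0, n)
    return a + (b - a) * (1.0 - np.cos(np.pi * s)) / 2.0


def _gait_template(p: GaitTemplateParams, off_ml: float, off_ap: float,
                   fs: float, tail: float = 1.0):
    """Noise-free template and ground-truth phase boundaries (s)."""
    n_cue = int(round(p.cue_time * fs))
    n_load = int(round(p.loading_duration * fs))
    n_unload = int(round(p.unloading_duration * fs))
    n_tail = int(round(tail * fs))
    if min(n_load, n_unload) < 2:
        raise ValueError("phase durations too short for the sampling rate")
    peak_ml = off_ml + p.apa_ml_amplitude
    peak_ap = off_ap + p.apa_ap_amplitude
    # unloading reverses past baseline toward the stance side
    end_ml = off_ml - 0.5 * p.apa_ml_amplitude
    end_ap = off_ap - 0.5 * p.apa_ap_amplitude
    ml = np.concatenate([
        np.full(n_cue, off_ml),
        _cosine_ramp(off_ml, peak_ml, n_load),
        _cosine_ramp(peak_ml, end_ml, n_unload)[1:],
        np.full(n_tail, end_ml),
    ])
    ap = np.concatenate([
        np.full(n_cue, off_ap),
        _cosine_ramp(off_ap, peak_ap, n_load),
        _cosine_ramp(peak_ap, end_ap, n_unload)[1:],
        np.full(n_tail, end_ap),
    ])
    t_onset = p.cue_time
    t_peak = p.cue_time + (n_load - 1) / fs
    # unloading truth boundary: first recrossing of the baseline ML level
    unl = _cosine_ramp(peak_ml, end_ml, n_unload)
    sign = np.sign(p.apa_ml_amplitude) or 1.0
    cross = np.nonzero(sign * (unl - off_ml) <= 0)[0]
    t_end = t_peak + int(cross[0] if cross.size else n_unload - 1) / fs
    return ml, ap, {"cue_time": float(p.cue_time), "onset": float(t_onset),
                    "loading_end": float(t_peak), "unloading_end": float(t_end)}


def simulate_gait_initiation_trial(
    profile: SubjectProfile,
    fs: float = 1000.0,
    seed: int = 0,
    tail: float = 1.0,
) -> ForcePlateTrial:
    """Simulate a gait-initiation trial: baseline hold, cue, APA, reversal."""
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    rng = np.random.default_rng(seed)
    p = profile.gait
    s = profile.sway
    ml, ap, events = _gait_template(p, s.cop_offset_ml, s.cop_offset_ap, fs, tail)
    if p.template_noise_sd > 0:
        ml = ml + p.template_noise_sd * rng.standard_normal(len(ml))
        ap = ap + p.template_noise_sd * rng.standard_normal(len(ap))
    ch = _channels_from_cop(ml, ap, profile.mass, fs, rng)
    n = len(ml)
    meta = {
        "subject_id": profile.subject_id,
        "group": profile.group,
        "session": profile.session,
        "test_type": "gait_initiation",
        "events": events,
    }
    return ForcePlateTrial(fs=fs, t=np.arange(n) / fs, **ch, meta=meta)


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the target study: 6 healthy subjects (one session) and
    6+6 PD subjects (pre and post sessions), standing 30 s and one
    gait-initiation trial per subject-session, sampled at 1000 Hz.
    """

    n_healthy: int = 6
    n_pd_control: int = 6
    n_pd_tpei: int = 6
    standing_duration: float = 30.0
    fs: float = 1000.0
    intervention_lambda: float = 0.6
    #: log-normal SD of per-subject multiplicative jitter on sway sigmas
    subject_jitter: float = 0.10
    #: residual session-to-session drift applied to non-intervention repeats
    session_jitter: float = 0.03
    #: group presets; None -> the package defaults above
    healthy_sway_params: SwayParams | None = None
    pd_sway_params: SwayParams | None = None
    healthy_gait_params: GaitTemplateParams | None = None
    pd_gait_params: GaitTemplateParams | None = None

    def __post_init__(self) -> None:
        if min(self.n_healthy, self.n_pd_control, self.n_pd_tpei) < 1:
            raise ValueError("each group must contain at least one subject")
        if not 0.0 <= self.intervention_lambda <= 1.0:
            raise ValueError("intervention_lambda must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Per-subject generative parameters and intended effect directions."""

    seed: int
    config: CohortConfig
    profiles: dict[str, dict[str, SubjectProfile]]  # subject_id -> session -> profile
    effect_directions: dict[str, str] = field(default_factory=lambda: {
        "rms_ml_standing": "pd > healthy",
        "pl_ap_standing": "pd > healthy",
        "ldisp_gait": "pd < healthy",
    })

    def group_of(self, subject_id: str) -> str:
        sessions = self.profiles[subject_id]
        return next(iter(sessions.values())).group


def _jitter_sway(p: SwayParams, rng: np.random.Generator, sd: float) -> SwayParams:
    if sd == 0:
        return p
    f = np.exp(sd * rng.standard_normal(4))
    return dataclasses.replace(
        p,
        sigma_ml=p.sigma_ml * f[0], sigma_ap=p.sigma_ap * f[1],
        theta_ml=p.theta_ml * f[2], theta_ap=p.theta_ap * f[3],
    )


def _jitter_gait(p: GaitTemplateParams, rng: np.random.Generator, sd: float) -> GaitTemplateParams:
    if sd == 0:
        return p
    f = np.exp(sd * rng.standard_normal(2))
    return dataclasses.replace(
        p,
        apa_ml_amplitude=p.apa_ml_amplitude * f[0],
        apa_ap_amplitude=p.apa_ap_amplitude * f[1],
    )


def _demographics(group: str, rng: np.random.Generator) -> tuple[float, str, float, float]:
    """Age, sex, BMI, mass in the ranges of the target study population."""
    if group == "healthy":
        age = float(np.clip(rng.normal(24.0, 2.0), 20, 32))
    else:
        age = float(np.clip(rng.normal(60.0, 12.0), 36, 80))
    sex = "M" if rng.random() < 0.65 else "F"
    bmi = float(np.clip(rng.normal(24.5, 3.5), 18.5, 34))
    height = rng.normal(1.75, 0.07) if sex == "M" else rng.normal(1.62, 0.06)
    mass = float(bmi * height**2)
    return age, sex, bmi, mass


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> tuple[list[ForcePlateTrial], CohortTruth]:
    """Generate standing + gait trials for a full cohort.

    Healthy subjects contribute one session ('single'); each PD subject
    contributes 'pre' and 'post'. TPEI post-session parameters are shifted
    toward the healthy preset by ``config.intervention_lambda``; control
    post sessions only drift by the residual session jitter.
    """
    master = np.random.default_rng(seed)
    profiles: dict[str, dict[str, SubjectProfile]] = {}
    trials: list[ForcePlateTrial] = []

    roster: list[tuple[str, str]] = []
    roster += [("healthy", f"H{i+1:02d}") for i in range(config.n_healthy)]
    roster += [("pd_control", f"C{i+1:02d}") for i in range(config.n_pd_control)]
    roster += [("pd_tpei", f"E{i+1:02d}") for i in range(config.n_pd_tpei)]

    trial_seed_stream = np.random.default_rng(master.integers(2**31))
    for group, sid in roster:
        sub_rng = np.random.default_rng(master.integers(2**31))
        age, sex, bmi, mass = _demographics(group, sub_rng)
        h_sway = config.healthy_sway_params or healthy_sway()
        p_sway = config.pd_sway_params or pd_sway()
        h_gait = config.healthy_gait_params or healthy_gait()
        p_gait = config.pd_gait_params or pd_gait()
        base_sway = h_sway if group == "healthy" else p_sway
        base_gait = h_gait if group == "healthy" else p_gait
        sway = _jitter_sway(base_sway, sub_rng, config.subject_jitter)
        gait = _jitter_gait(base_gait, sub_rng, config.subject_jitter)
        sessions = ("single",) if group == "healthy" else ("pre", "post")
        profiles[sid] = {}
        for session in sessions:
            s_sway, s_gait = sway, gait
            if session == "post":
                if group == "pd_tpei":
                    s_sway = blend_sway(sway, h_sway, config.intervention_lambda)
                    s_gait = blend_gait(gait, h_gait, config.intervention_lambda)
                s_sway = _jitter_sway(s_sway, sub_rng, config.session_jitter)
                s_gait = _jitter_gait(s_gait, sub_rng, config.session_jitter)
            prof = SubjectProfile(
                subject_id=sid, group=group, session=session,
                age=age, sex=sex, bmi=bmi, mass=mass, sway=s_sway, gait=s_gait,
            )
            profiles[sid][session] = prof
            trials.append(simulate_standing_trial(
                prof, config.standing_duration, config.fs,
                seed=int(trial_seed_stream.integers(2**31))))
            trials.append(simulate_gait_initiation_trial(
                prof, config.fs, seed=int(trial_seed_stream.integers(2**31))))

    truth = CohortTruth(seed=seed, config=config, profiles=profiles)
    return trials, truth


def write_cohort(
    trials: list[ForcePlateTrial],
    truth: CohortTruth,
    outdir: str | os.PathLike,
) -> None:
    """Write trials in the ingest CSV dialect plus metadata and truth files."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    meta_rows = []
    for trial in trials:
        m = trial.meta
        fname = f"{m['subject_id']}_{m['session']}_{m['test_type']}.csv"
        write_trial(trial, os.path.join(outdir, fname))
        meta_rows.append({
            "file": fname, "subject_id": m["subject_id"], "group": m["group"],
            "session": m["session"], "test_type": m["test_type"],
            "cue_time": m["events"].get("cue_time", ""),
        })
    subj_rows = []
    for sid, sessions in truth.profiles.items():
        p = next(iter(sessions.values()))
        subj_rows.append({
            "subject_id": sid, "group": p.group, "age": round(p.age, 1),
            "sex": p.sex, "bmi": round(p.bmi, 2), "mass": round(p.mass, 2),
        })
    pd.DataFrame(meta_rows).to_csv(os.path.join(outdir, "trials.csv"), index=False)
    pd.DataFrame(subj_rows).to_csv(os.path.join(outdir, "subjects.csv"), index=False)
    truth_json = {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "effect_directions": truth.effect_directions,
        "profiles": {
            sid: {
                ses: {
                    "sway": dataclasses.asdict(p.sway),
                    "gait": dataclasses.asdict(p.gait),
                }
                for ses, p in sessions.items()
            }
            for sid, sessions in truth.profiles.items()
        },
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1)
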