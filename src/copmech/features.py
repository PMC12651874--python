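"""Mechanics-informed feature extraction from COP trajectories.

Standing (stabilometry) features follow standard conventions: path length
is the summed absolute first difference per axis (and the planar Euclidean
sum), RMS and variance are computed on the demeaned series so that
``var == rms**2`` holds exactly, mean velocity is path length over
duration, and sway area is the 95% prediction-ellipse area
``pi * chi2_2(0.95) * sqrt(det(cov))``.

Gait-initiation features quantify the anticipatory postural adjustment:
the trajectory is segmented into loading (onset to the first mediolateral
extremum) and unloading (extremum back to the baseline crossing) phases,
and net displacement / mean velocity are reported per phase and axis.
``ldisp`` — loading-phase ML displacement — is the APA amplitude.

Feature-table assembly merges the standing, gait and channel-SD blocks
with demographics into one row per subject-session, with column
provenance retained and optional joint z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .preprocess import COPTrajectory, ForcePlateTrial

__all__ = [
    "StandingFeatures",
    "GaitPhases",
    "GaitInitFeatures",
    "SignalSDFeatures",
    "FeatureTable",
    "standing_features",
    "segment_gait_initiation",
    "gait_features",
    "signal_sd_features",
    "build_feature_table",
    "standardize",
]

#: chi-square(2 df) quantile at 0.95 for the prediction-ellipse area.
CHI2_95_2DF = float(chi2.ppf(0.95, 2))


@dataclass(frozen=True)
class StandingFeatures:
    pl_ml: float
    pl_ap: float
    pl_total: float
    rms_ml: float
    rms_ap: float
    var_ml: float
    var_ap: float
    vmean_ml: float
    vmean_ap: float
    vmean_total: float
    sway_area: float

    def as_dict(self, prefix: str = "stand_") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class GaitPhases:
    """Loading/unloading boundaries (seconds, trial clock) with diagnostics."""

    onset: float
    loading_end: float
    unloading_end: float
    baseline_sd: float
    threshold: float
    direction: float  # +1/-1, sign of the detected ML excursion

    def __post_init__(self) -> None:
        if not self.onset < self.loading_end < self.unloading_end:
            raise ValueError("phase boundaries must be strictly ordered")


@dataclass(frozen=True)
class GaitInitFeatures:
    ldisp: float
    load_disp_ml: float
    load_disp_ap: float
    unload_disp_ml: float
    unload_disp_ap: float
    load_vel_ml: float
    load_vel_ap: float
    unload_vel_ml: float
    unload_vel_ap: float

    def as_dict(self, prefix: str = "gait_") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class SignalSDFeatures:
    sd_fx: float
    sd_fy: float
    sd_fz: float
    sd_mx: float
    sd_my: float
    sd_mz: float
    sd_cop_ml: float
    sd_cop_ap: float

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


def _valid_xy(cop: COPTrajectory) -> tuple[np.ndarray, np.ndarray]:
    if not np.any(cop.valid_mask):
        raise ValueError("all samples invalid: no loaded COP data")
    ml = cop.ml[cop.valid_mask]
    ap = cop.ap[cop.valid_mask]
    return ml, ap


def standing_features(cop: COPTrajectory) -> StandingFeatures:
    """Compute the quiet-standing sway feature block.

    RMS/variance use the demeaned series with the population (1/n)
    normalization so ``var == rms**2`` holds identically; channel-SD
    features elsewhere use the sample (n-1) convention.
    """
    ml, ap = _valid_xy(cop)
    if len(ml) < 2:
        raise ValueError("need at least two valid samples")
    duration = len(ml) / cop.fs
    dml = np.diff(ml)
    dap = np.diff(ap)
    pl_ml = float(np.sum(np.abs(dml)))
    pl_ap = float(np.sum(np.abs(dap)))
    pl_total = float(np.sum(np.hypot(dml, dap)))
    ml0 = ml - ml.mean()
    ap0 = ap - ap.mean()
    var_ml = float(np.mean(ml0**2))
    var_ap = float(np.mean(ap0**2))
    if var_ml * var_ap == 0.0:
        area = 0.0
    else:
        cov = np.cov(np.vstack([ml, ap]), ddof=1)
        det = max(float(np.linalg.det(cov)), 0.0)
        area = float(np.pi * CHI2_95_2DF * np.sqrt(det))
    return StandingFeatures(
        pl_ml=pl_ml, pl_ap=pl_ap, pl_total=pl_total,
        rms_ml=float(np.sqrt(var_ml)), rms_ap=float(np.sqrt(var_ap)),
        var_ml=var_ml, var_ap=var_ap,
        vmean_ml=pl_ml / duration, vmean_ap=pl_ap / duration,
        vmean_total=pl_total / duration, sway_area=area,
    )


def segment_gait_initiation(
    cop: COPTrajectory,
    cue_time: float,
    baseline_window: float = 2.0,
    k_threshold: float = 3.0,
    min_sustain: float = 0.05,
) -> GaitPhases:
    """Detect APA onset and the loading/unloading boundaries.

    Onset is the first post-cue sample at which the planar deviation from
    the baseline mean exceeds ``k_threshold`` baseline SDs, sustained for
    ``min_sustain`` seconds. Loading ends at the subsequent extremum of
    the dominant ML excursion; unloading ends when the ML series recrosses
    its baseline level (or at the trajectory end).

    Times are on the trial clock (``cop.meta['t0']`` aware).
    """
    t0 = float(cop.meta.get("t0", 0.0))
    fs = cop.fs
    t = cop.t
    if cue_time <= t[0]:
        raise ValueError("cue precedes the available trajectory")
    i_cue = int(np.searchsorted(t, cue_time))
    i_base0 = max(0, i_cue - int(round(baseline_window * fs)))
    if i_cue - i_base0 < 2:
        raise ValueError("baseline window must contain at least two samples")
    ml0 = float(np.mean(cop.ml[i_base0:i_cue]))
    ap0 = float(np.mean(cop.ap[i_base0:i_cue]))
    dev = np.hypot(cop.ml - ml0, cop.ap - ap0)
    base_sd = float(np.std(dev[i_base0:i_cue], ddof=1))
    thr = k_threshold * base_sd
    n_sustain = max(1, int(round(min_sustain * fs)))
    above = dev > thr
    # sustained[i] True iff all of above[i:i+n_sustain] hold
    counts = np.convolve(above.astype(float), np.ones(n_sustain), mode="valid")
    sustained = counts >= n_sustain - 0.5
    cand = np.nonzero(sustained[i_cue:])[0]
    if cand.size == 0:
        raise ValueError("no initiation detected after the cue")
    onset_idx = i_cue + int(cand[0])
    # dominant ML excursion direction over a short post-onset horizon
    horizon = slice(onset_idx, min(len(t), onset_idx + int(2.0 * fs)))
    s = cop.ml[horizon] - ml0
    direction = 1.0 if s[np.argmax(np.abs(s))] >= 0 else -1.0
    peak_rel = int(np.argmax(direction * s))
    peak_idx = onset_idx + peak_rel
    if peak_idx <= onset_idx:
        # excursion peaks immediately: treat the next sample as the extremum
        peak_idx = onset_idx + 1
    after = direction * (cop.ml[peak_idx:] - ml0)
    recross = np.nonzero(after <= 0)[0]
    end_idx = peak_idx + (int(recross[0]) if recross.size else len(after) - 1)
    end_idx = max(end_idx, peak_idx + 1)
    end_idx = min(end_idx, len(t) - 1)
    return GaitPhases(
        onset=float(t[onset_idx]),
        loading_end=float(t[peak_idx]),
        unloading_end=float(t[end_idx]),
        baseline_sd=base_sd,
        threshold=thr,
        direction=direction,
    )


def gait_features(cop: COPTrajectory, phases: GaitPhases) -> GaitInitFeatures:
    """Net displacement and mean velocity per phase and axis."""
    t = cop.t
    i_on = int(np.searchsorted(t, phases.onset))
    i_peak = int(np.searchsorted(t, phases.loading_end))
    i_end = int(np.searchsorted(t, phases.unloading_end))
    i_end = min(i_end, len(t) - 1)
    if i_peak <= i_on or i_end <= i_peak:
        raise ValueError("zero-length gait phase")
    d_load = (phases.loading_end - phases.onset)
    d_unload = (phases.unloading_end - phases.loading_end)
    ld_ml = float(abs(cop.ml[i_peak] - cop.ml[i_on]))
    ld_ap = float(abs(cop.ap[i_peak] - cop.ap[i_on]))
    ud_ml = float(abs(cop.ml[i_end] - cop.ml[i_peak]))
    ud_ap = float(abs(cop.ap[i_end] - cop.ap[i_peak]))
    return GaitInitFeatures(
        ldisp=ld_ml,
        load_disp_ml=ld_ml, load_disp_ap=ld_ap,
        unload_disp_ml=ud_ml, unload_disp_ap=ud_ap,
        load_vel_ml=ld_ml / d_load, load_vel_ap=ld_ap / d_load,
        unload_vel_ml=ud_ml / d_unload, unload_vel_ap=ud_ap / d_unload,
    )


def signal_sd_features(trial: ForcePlateTrial, cop: COPTrajectory) -> SignalSDFeatures:
    """Sample standard deviation (n-1) of each raw channel and COP axis."""
    if trial.n_samples < 2 or cop.n_samples < 2:
        raise ValueError("need at least two samples for a standard deviation")
    sd = {k: float(np.std(v, ddof=1)) for k, v in trial.channels().items()}
    return SignalSDFeatures(
        sd_fx=sd["Fx"], sd_fy=sd["Fy"], sd_fz=sd["Fz"],
        sd_mx=sd["Mx"], sd_my=sd["My"], sd_mz=sd["Mz"],
        sd_cop_ml=float(np.std(cop.ml[cop.valid_mask], ddof=1)),
        sd_cop_ap=float(np.std(cop.ap[cop.valid_mask], ddof=1)),
    )


# ---------------------------------------------------------------------------
# Feature table

@dataclass
class FeatureTable:
    """Subject-session × feature matrix with provenance and scaling state."""

    df: pd.DataFrame  # index: (subject_id, session)
    provenance: dict[str, str]  # column -> block name
    standardized: bool = False
    scale_means: dict[str, float] = field(default_factory=dict)
    scale_sds: dict[str, float] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def subjects(self) -> list[str]:
        return [ix[0] for ix in self.df.index]

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        return self.df[columns or self.df.columns].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path)


SEX_CODES = {"M": 0.0, "F": 1.0}


def build_feature_table(
    records: list[dict],
    blocks: tuple[str, ...] = ("standing", "gait", "signal_sd", "demographics"),
    demographics: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble one row per subject-session from per-record feature blocks.

    Each record is a dict with keys ``subject_id``, ``session`` and any of
    the block payloads: ``standing`` (:class:`StandingFeatures`), ``gait``
    (:class:`GaitInitFeatures`), ``signal_sd`` (:class:`SignalSDFeatures`).
    Demographics (age, sex, bmi per subject) join by subject id; sex is
    coded M=0, F=1.
    """
    rows, provenance, seen = {}, {}, set()
    demo = None
    if demographics is not None:
        demo = demographics.set_index("subject_id") if "subject_id" in demographics.columns \
            else demographics
    for rec in records:
        key = (rec["subject_id"], rec.get("session", "single"))
        if key in seen:
            raise ValueError(f"duplicate subject-session record {key}")
        seen.add(key)
        row: dict[str, float] = {}
        for block in blocks:
            if block == "demographics":
                if demo is None:
                    raise ValueError("demographics block requested but no table given")
                if key[0] not in demo.index:
                    raise ValueError(f"record {key}: missing demographics row")
                d = demo.loc[key[0]]
                vals = {"age": float(d["age"]), "sex": SEX_CODES[str(d["sex"])],
                        "bmi": float(d["bmi"])}
            else:
                if block not in rec or rec[block] is None:
                    raise ValueError(f"record {key}: missing block {block!r}")
                vals = rec[block].as_dict()
            for col, v in vals.items():
                row[col] = float(v)
                provenance[col] = block
        rows[key] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject_id", "session"])
    df = df.sort_index()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing cells after assembly in columns {bad}")
    return FeatureTable(df=df, provenance=provenance)


def standardize(table: FeatureTable) -> FeatureTable:
    """Joint column-wise z-score over all rows (population SD).

    All rows entering an analysis — pre and post sessions together — share
    one scaling so they live in a common space for embedding/clustering.
    """
    if len(table.df) < 2:
        raise ValueError("need at least two rows to standardize")
    means = table.df.mean()
    sds = table.df.std(ddof=0)
    zero = sds[sds == 0.0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    df = (table.df - means) / sds
    return FeatureTable(
        df=df,
        provenance=dict(table.provenance),
        standardized=True,
        scale_means={c: float(means[c]) for c in df.columns},
        scale_sds={c: float(sds[c]) for c in df.columns},
    )
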