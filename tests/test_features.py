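"""Standing/gait feature extraction against analytic and quadrature oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copmech.features import (FeatureTable, build_feature_table, gait_features,
                              segment_gait_initiation, signal_sd_features,
                              standardize, standing_features)
from copmech.preprocess import COPTrajectory, compute_cop, preprocess_trial
from copmech.simulate import (GaitTemplateParams, simulate_cohort,
                              simulate_gait_initiation_trial, CohortConfig)

import pandas as pd


def _cop(ml, ap, fs):
    ml = np.asarray(ml, float)
    return COPTrajectory(ml=ml, ap=np.asarray(ap, float), fs=fs,
                         valid_mask=np.ones(len(ml), bool))


class TestStandingFeatures:
    def test_constant_cop_gives_zero_everything(self):
        f = standing_features(_cop(np.full(100, 5.0), np.full(100, -3.0), 100.0))
        assert f.pl_total == 0.0 and f.rms_ml == 0.0 and f.sway_area == 0.0

    def test_sinusoid_against_quadrature_oracle(self):
        """ap = r sin(2 pi f t), 10 cycles: PL = 4 r n, RMS = r/sqrt(2),
        vmean = PL / duration. Oracle values recomputed by dense quadrature
        of |r 2 pi f cos| agree with the closed forms."""
        r, f, cycles, fs = 5.0, 0.5, 10, 2000.0
        duration = cycles / f
        t = np.arange(0, duration, 1 / fs)
        ap = r * np.sin(2 * np.pi * f * t)
        feats = standing_features(_cop(np.zeros_like(ap), ap, fs))
        # quadrature oracle for the path length
        oracle_pl = np.trapezoid(np.abs(r * 2 * np.pi * f *
                                        np.cos(2 * np.pi * f * t)), t)
        assert oracle_pl == pytest.approx(4 * r * cycles, rel=1e-3)
        assert feats.pl_ap == pytest.approx(4 * r * cycles, rel=0.01)
        assert feats.rms_ap == pytest.approx(r / np.sqrt(2), rel=0.01)
        assert feats.vmean_ap == pytest.approx(4 * r * cycles / duration,
                                               rel=0.01)
        assert feats.pl_ml == 0.0

    def test_circle_sway_area_is_95pct_ellipse(self):
        """Uniform circle of radius r: cov = (r^2/2) I, so the 95%
        prediction ellipse has area chi2_2(0.95) pi r^2 / 2."""
        r, n = 5.0, 20000
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        feats = standing_features(_cop(r * np.cos(th), r * np.sin(th), 100.0))
        assert feats.sway_area == pytest.approx(5.991 * np.pi * r**2 / 2,
                                                rel=0.01)

    def test_variance_is_rms_squared(self, standing_trial):
        f = standing_features(preprocess_trial(standing_trial))
        assert f.var_ml == pytest.approx(f.rms_ml**2, rel=1e-9)
        assert f.var_ap == pytest.approx(f.rms_ap**2, rel=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_homogeneity_under_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        ml, ap = rng.standard_normal(200), rng.standard_normal(200)
        base = standing_features(_cop(ml, ap, 50.0))
        scaled = standing_features(_cop(c * ml, c * ap, 50.0))
        assert scaled.pl_total == pytest.approx(c * base.pl_total, rel=1e-9)
        assert scaled.rms_ml == pytest.approx(c * base.rms_ml, rel=1e-9)
        assert scaled.sway_area == pytest.approx(c**2 * base.sway_area,
                                                 rel=1e-6)

    def test_offset_invariance(self, rng):
        ml, ap = rng.standard_normal(300), rng.standard_normal(300)
        a = standing_features(_cop(ml, ap, 100.0))
        b = standing_features(_cop(ml + 40.0, ap - 15.0, 100.0))
        assert b.rms_ml == pytest.approx(a.rms_ml)
        assert b.pl_ap == pytest.approx(a.pl_ap)
        assert b.sway_area == pytest.approx(a.sway_area)

    def test_path_length_bounds_net_displacement(self, rng):
        ml = np.cumsum(rng.standard_normal(500))
        f = standing_features(_cop(ml, np.zeros_like(ml), 100.0))
        assert f.pl_ml >= abs(ml[-1] - ml[0]) - 1e-12


class TestGaitSegmentation:
    def test_noise_free_template_matches_truth(self, quiet_profile):
        trial = simulate_gait_initiation_trial(quiet_profile, fs=1000.0, seed=0)
        cop = compute_cop(trial)
        ev = trial.meta["events"]
        ph = segment_gait_initiation(cop, cue_time=3.0, baseline_window=2.0)
        assert ph.loading_end == pytest.approx(ev["loading_end"], abs=1.5e-3)
        assert ph.unloading_end == pytest.approx(ev["unloading_end"], abs=0.05)

    def test_step_onset_at_threshold_crossing(self):
        fs = 1000.0
        n = 5000
        rng = np.random.default_rng(0)
        ml = 0.1 * rng.standard_normal(n)
        sd = np.std(np.hypot(ml[:3000] - ml[:3000].mean(), 0), ddof=1)
        ml[4000:] += 10 * sd + 1.0  # unambiguous step at t* = 4 s
        ph = segment_gait_initiation(_cop(ml, np.zeros(n), fs), cue_time=3.0)
        assert ph.onset == pytest.approx(4.0, abs=2e-3)

    def test_no_initiation_raises(self):
        rng = np.random.default_rng(1)
        ml = 0.1 * rng.standard_normal(4000)
        with pytest.raises(ValueError, match="no initiation"):
            segment_gait_initiation(_cop(ml, np.zeros_like(ml), 1000.0),
                                    cue_time=3.0)

    def test_noisy_boundaries_within_50ms_most_of_the_time(self, healthy_profile):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            trial = simulate_gait_initiation_trial(healthy_profile, fs=500.0,
                                                   seed=seed)
            cop = preprocess_trial(trial)
            ev = trial.meta["events"]
            ph = segment_gait_initiation(cop, cue_time=3.0, baseline_window=1.0)
            if abs(ph.loading_end - ev["loading_end"]) <= 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestGaitFeatures:
    def test_noiseless_ldisp_equals_amplitude(self, quiet_profile):
        prof = dataclasses.replace(
            quiet_profile,
            gait=GaitTemplateParams(apa_ml_amplitude=30.0,
                                    template_noise_sd=0.0))
        trial = simulate_gait_initiation_trial(prof, fs=1000.0, seed=0)
        cop = compute_cop(trial)
        ph = segment_gait_initiation(cop, cue_time=3.0)
        f = gait_features(cop, ph)
        assert f.ldisp == pytest.approx(30.0, abs=0.1)

    def test_velocity_is_displacement_over_duration(self, gait_trial):
        cop = preprocess_trial(gait_trial)
        ph = segment_gait_initiation(cop, cue_time=3.0, baseline_window=1.0)
        f = gait_features(cop, ph)
        assert f.load_vel_ml == pytest.approx(
            f.load_disp_ml / (ph.loading_end - ph.onset))

    def test_pd_amplitude_ratio_recovered_over_seeds(self, healthy_profile):
        """Generated PD/healthy APA scale factor 0.6 recovered within 5%."""
        pd_prof = dataclasses.replace(
            healthy_profile,
            gait=dataclasses.replace(healthy_profile.gait,
                                     apa_ml_amplitude=0.6 * 30.0))
        ratios = []
        for seed in range(50):
            vals = {}
            for name, prof in (("h", healthy_profile), ("p", pd_prof)):
                trial = simulate_gait_initiation_trial(prof, fs=250.0,
                                                       seed=seed)
                cop = preprocess_trial(trial)
                ph = segment_gait_initiation(cop, cue_time=3.0,
                                             baseline_window=1.0)
                vals[name] = gait_features(cop, ph).ldisp
            ratios.append(vals["p"] / vals["h"])
        assert np.mean(ratios) == pytest.approx(0.6, rel=0.05)


class TestSignalSD:
    def test_alternating_channel_sd(self, standing_trial):
        """x = +-a alternating, even n: sample SD = a sqrt(n/(n-1))."""
        n, a = 100, 3.0
        alt = a * (-1.0) ** np.arange(n)
        assert np.std(alt, ddof=1) == pytest.approx(a * np.sqrt(n / (n - 1)))
        trial = standing_trial
        trial.Fx[:] = alt[: trial.n_samples] if n >= trial.n_samples else 0
        # direct contract: SD features match numpy's sample SD per channel
        cop = compute_cop(trial)
        f = signal_sd_features(trial, cop)
        assert f.sd_fz == pytest.approx(np.std(trial.Fz, ddof=1))
        assert f.sd_cop_ml == pytest.approx(np.std(cop.ml, ddof=1))

    def test_affine_rescale_scales_sd(self, standing_trial):
        cop = compute_cop(standing_trial)
        base = signal_sd_features(standing_trial, cop)
        scaled_trial = dataclasses.replace(
            standing_trial, My=3.0 * standing_trial.My)
        scaled = signal_sd_features(scaled_trial, cop)
        assert scaled.sd_my == pytest.approx(3.0 * base.sd_my)


class TestFeatureTable:
    def _records(self):
        cfg = CohortConfig(n_healthy=2, n_pd_control=2, n_pd_tpei=2,
                           standing_duration=8.0, fs=100.0)
        trials, truth = simulate_cohort(cfg, seed=3)
        from copmech.pipeline import _demographics_frame, extract_features
        return extract_features(trials), _demographics_frame(truth)

    def test_row_bookkeeping(self):
        records, demo = self._records()
        table = build_feature_table(records, demographics=demo)
        # 2 healthy x 1 + 4 PD x 2 = 10 subject-sessions
        assert len(table.df) == 10
        assert table.provenance["stand_rms_ml"] == "standing"
        assert table.provenance["age"] == "demographics"
        assert set(table.df["sex"].unique()) <= {0.0, 1.0}

    def test_duplicate_key_rejected(self):
        records, demo = self._records()
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(records + [records[0]], demographics=demo)

    def test_missing_block_names_record(self):
        records, demo = self._records()
        broken = dict(records[0])
        del broken["gait"]
        with pytest.raises(ValueError, match="gait"):
            build_feature_table([broken] + records[1:], demographics=demo)

    def test_sd_only_block_gives_one_row_per_subject_session(self):
        records, demo = self._records()
        table = build_feature_table(records, blocks=("signal_sd",))
        assert list(table.df.columns) == [
            "sd_fx", "sd_fy", "sd_fz", "sd_mx", "sd_my", "sd_mz",
            "sd_cop_ml", "sd_cop_ap"]

    def test_standardize_postcondition_and_idempotence(self):
        records, demo = self._records()
        table = build_feature_table(records, demographics=demo)
        table.df = table.df.drop(columns=["sex"])  # may be constant at n=6
        z = standardize(table)
        assert np.allclose(z.df.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.df.std(ddof=0), 1.0, atol=1e-9)
        zz = standardize(z)
        assert np.allclose(zz.df.to_numpy(), z.df.to_numpy(), atol=1e-12)

    def test_standardize_rejects_constant_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        table = FeatureTable(df=df, provenance={})
        with pytest.raises(ValueError, match="b"):
            standardize(table)
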