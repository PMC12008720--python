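"""Cohort generator: determinism, monotone severity encodings, group
structure and ground-truth bookkeeping."""

import numpy as np
import pytest

from taugraph.pet import EARLY_METAVOI, RegionTau, aggregate_voi
from taugraph.preprocess import epoch_recording, relative_band_power, welch_psd
from taugraph.synthetic import (DEFAULT_LOADINGS, VOXEL_COUNTS,
                                Cohort, CohortConfig, simulate_cohort,
                                simulate_neuropsych, simulate_subject_eeg,
                                simulate_tau_profile, write_cohort)


def theta_alpha_ratio(rec):
    ps = welch_psd(epoch_recording(rec, 60.0, 20.0))
    theta = relative_band_power(ps, (4.0, 8.0)).mean()
    alpha = relative_band_power(ps, (8.0, 13.0)).mean()
    return theta / alpha


class TestSubjectEEG:
    def test_bit_identical_for_same_inputs(self, small_config):
        a = simulate_subject_eeg(small_config, 0.4, 123)
        b = simulate_subject_eeg(small_config, 0.4, 123)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self, small_config):
        a = simulate_subject_eeg(small_config, 0.4, 1)
        b = simulate_subject_eeg(small_config, 0.4, 2)
        assert not np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("severity", [-0.1, 1.5])
    def test_severity_bounds_enforced(self, small_config, severity):
        with pytest.raises(ValueError, match="severity"):
            simulate_subject_eeg(small_config, severity, 0)

    def test_short_duration_rejected_at_config(self):
        with pytest.raises(ValueError, match="duration"):
            CohortConfig(duration_s=70)

    def test_slowing_with_severity(self):
        """Theta/alpha power ratio strictly larger at severity 1 than 0,
        averaged over seeds."""
        cfg = CohortConfig(seed=0, n_channels=4, duration_s=100, fs=128)
        lo = np.mean([theta_alpha_ratio(simulate_subject_eeg(cfg, 0.0, s))
                      for s in range(20)])
        hi = np.mean([theta_alpha_ratio(simulate_subject_eeg(cfg, 1.0, s))
                      for s in range(20, 40)])
        assert hi > lo

    def test_uncoupled_channels_have_null_wpli(self):
        from taugraph.connectivity import wpli_matrix
        from taugraph.preprocess import bandpass

        cfg = CohortConfig(seed=0, n_channels=4, duration_s=100, fs=128,
                           coupling_base=0.0)
        vals = []
        for s in range(5):
            rec = simulate_subject_eeg(cfg, 0.0, 50 + s)
            ep = epoch_recording(bandpass(rec, 0.5, 40.0))
            vals.append(wpli_matrix(ep, (8.0, 13.0)).W[0, 1])
        assert np.mean(vals) < 0.35  # near Monte-Carlo null, far from 1

    def test_eyes_open_halves_alpha(self):
        cfg = CohortConfig(seed=0, n_channels=4, duration_s=100, fs=128,
                           noise_sd=0.0, theta_amp=0.0)
        ec = simulate_subject_eeg(cfg, 0.0, 9, condition="eyes_closed")
        eo = simulate_subject_eeg(cfg, 0.0, 9, condition="eyes_open")
        assert eo.samples.std() == pytest.approx(ec.samples.std() / 2, rel=0.01)


class TestTauProfile:
    def test_noiseless_severity_zero_returns_bases(self):
        cfg = CohortConfig(tau_noise_sd=0.0)
        tau = simulate_tau_profile(0.0, cfg, 0)
        for region, base in cfg.tau_bases.items():
            assert tau[region] == pytest.approx(base)

    def test_group_means_ordered_over_seeds(self):
        """Early-metaVOI DVR group means ordered CU- < CU+ < prodromal."""
        cfg = CohortConfig()
        ok = 0
        rng = np.random.default_rng(0)
        for _ in range(20):
            means = {}
            for group, (lo, hi) in cfg.severity_ranges.items():
                vals = []
                for _ in range(50):
                    sev = rng.uniform(lo, hi)
                    tau = simulate_tau_profile(sev, cfg, int(rng.integers(2**31)))
                    regions = [RegionTau(r, tau[r], VOXEL_COUNTS[r])
                               for r in EARLY_METAVOI.members]
                    vals.append(aggregate_voi(regions, EARLY_METAVOI))
                means[group] = np.mean(vals)
            ok += means["CU-"] < means["CU+"] < means["prodromal"]
        assert ok == 20  # forced by the monotone construction

    def test_perirhinal_entorhinal_gap_grows_with_severity(self):
        cfg = CohortConfig(tau_noise_sd=0.0)
        gaps = [simulate_tau_profile(s, cfg, 0)["perirhinal"]
                - simulate_tau_profile(s, cfg, 0)["entorhinal"]
                for s in (0.0, 0.5, 1.0)]
        assert gaps[0] < gaps[1] < gaps[2]

    def test_perirhinal_steepest_enforced(self):
        cfg = CohortConfig()
        cfg.tau_slopes = dict(cfg.tau_slopes, fusiform=5.0)
        with pytest.raises(ValueError, match="perirhinal"):
            simulate_tau_profile(0.5, cfg, 0)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(tau_bases={"entorhinal": -1.0})


class TestNeuropsych:
    def test_noiseless_scores_have_rank_two_structure(self, rng):
        X = np.array([simulate_neuropsych(rng.standard_normal(2),
                                          DEFAULT_LOADINGS, 0.0, i)
                      for i in range(200)])
        sv = np.linalg.svd(X - X.mean(0), compute_uv=False)
        assert sv[2] < 1e-8 * sv[0]

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            simulate_neuropsych(np.zeros(3), DEFAULT_LOADINGS, 0.1, 0)
        with pytest.raises(ValueError):
            simulate_neuropsych(np.zeros(2), DEFAULT_LOADINGS[:, :1], 0.1, 0)

    def test_zero_loadings_give_pure_noise(self, rng):
        X = np.array([simulate_neuropsych(rng.standard_normal(2),
                                          np.zeros((10, 2)), 1.0, i)
                      for i in range(100)])
        R = np.corrcoef(X, rowvar=False)
        off = R[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 0.15


class TestCohort:
    def test_reference_design_66_rows(self):
        cohort = simulate_cohort(CohortConfig(seed=1, n_channels=4))
        counts = cohort.subjects["group"].value_counts()
        assert len(cohort.subjects) == 66
        assert counts["CU-"] == 37 and counts["CU+"] == 14 \
            and counts["prodromal"] == 15

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_cohort(CohortConfig(n_per_group={}))

    def test_amyloid_consistent_with_group(self):
        cohort = simulate_cohort(CohortConfig(seed=2, n_channels=4))
        t = cohort.subjects
        assert (t.loc[t.group == "CU-", "cl_amyloid"] < 23.5).all()
        assert (t.loc[t.group != "CU-", "cl_amyloid"] > 23.5).all()
        assert (t.loc[t.group == "CU-", "amyloid_status"] == "negative").all()

    def test_severity_withheld_from_subject_table(self):
        cohort = simulate_cohort(CohortConfig(seed=3, n_channels=4))
        assert "severity" not in cohort.subjects.columns
        assert len(cohort.ground_truth.severity) == len(cohort.subjects)

    def test_serialization_deterministic(self, tmp_path):
        for d in ("a", "b"):
            write_cohort(simulate_cohort(CohortConfig(seed=7, n_channels=4)),
                         tmp_path / d)
        for name in ("cohort.tsv", "ground_truth.tsv", "config.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_recordings_regenerated_identically(self):
        cohort = simulate_cohort(CohortConfig(
            seed=4, n_channels=4, duration_s=100, fs=128,
            n_per_group={"CU-": 2, "CU+": 1, "prodromal": 1}))
        sid = cohort.subjects["subject_id"].iloc[0]
        a = cohort.recording(sid)
        b = cohort.recording(sid)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_uniform_coupling_gives_identical_metrics(self):
        """With every noise source off and coupling independent of severity,
        the wPLI graph saturates and all subjects share the same metrics."""
        from taugraph.pipeline import AnalysisConfig, build_feature_table

        cfg = CohortConfig(seed=5, n_channels=4, duration_s=100, fs=128,
                           noise_sd=0.0, theta_amp=0.0, tau_noise_sd=0.0,
                           coupling_slope=0.0,
                           n_per_group={"CU-": 3, "CU+": 1, "prodromal": 1})
        tab = build_feature_table(simulate_cohort(cfg),
                                  AnalysisConfig(bands={"alpha": (8., 13.)}),
                                  include_subsets=False)
        cu = tab[tab.group == "CU-"]
        assert cu["C"].std() < 1e-9
        assert cu["L"].std() < 1e-9

    def test_ground_truth_coupling_matches_recording_draws(self):
        cfg = CohortConfig(seed=6, n_channels=4, duration_s=100, fs=128,
                           n_per_group={"CU-": 1, "CU+": 1, "prodromal": 1})
        cohort = simulate_cohort(cfg)
        sid = cohort.subjects["subject_id"].iloc[0]
        lags = cohort.ground_truth.channel_lags[sid]
        assert lags.shape == (4,)
        assert (lags >= 1.0).all() and (lags <= 4.0).all()
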