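import numpy as np
import pytest
from scipy import stats as sst

import rsdelta as rd
from rsdelta.synthetic import ConfigurationError


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = rd.CohortConfig(n_per_group=(2, 2, 2), duration_s=12.0, seed=5)
        recs1, meta1, truth1 = rd.generate_cohort(cfg)
        recs2, meta2, truth2 = rd.generate_cohort(cfg)
        for a, b in zip(recs1, recs2):
            assert np.array_equal(a.data, b.data)
        assert meta1.equals(meta2)
        assert truth1.groups == truth2.groups

    def test_different_seed_differs(self):
        c1 = rd.CohortConfig(n_per_group=(2, 2, 2), duration_s=12.0, seed=5)
        c2 = rd.CohortConfig(n_per_group=(2, 2, 2), duration_s=12.0, seed=6)
        r1, _, _ = rd.generate_cohort(c1)
        r2, _, _ = rd.generate_cohort(c2)
        assert not np.array_equal(r1[0].data, r2[0].data)


class TestCohortStructure:
    def test_group_sizes_and_labels(self):
        cfg = rd.CohortConfig(n_per_group=(30, 19, 13), duration_s=4.0,
                              artifact_rate=0.0, eea_event_rate=0.0,
                              tirda_rate=0.0, seed=1)
        recs, meta, truth = rd.generate_cohort(cfg)
        assert len(recs) == 62
        counts = meta["group"].value_counts()
        assert counts["Nold"] == 30
        assert counts["noADMCI-noEEA"] == 19
        assert counts["noADMCI-EEA"] == 13
        assert set(truth.groups) == set(meta["subject_id"])
        assert meta["mmse"].between(0, 30).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.CohortConfig(n_per_group=(1, 5, 5))
        with pytest.raises(ConfigurationError):
            rd.CohortConfig(eea_event_rate=-1.0)
        with pytest.raises(ConfigurationError):
            rd.CohortConfig(iaf_mean=20.0)


class TestBackground:
    def test_sample_count(self):
        rec = rd.synthesize_background(128.0, 180.0, seed=0)
        assert rec.n_samples == 23040

    def test_psd_peak_at_requested_iaf(self):
        """The 6-14 Hz maximum of the Welch PSD lies within one bin of the
        requested alpha frequency."""
        for iaf in (8.5, 9.5, 11.0):
            rec = rd.synthesize_background(128.0, 60.0, iaf=iaf, seed=3)
            psd = rd.welch_psd(rec, rd.segment_epochs(rec, span_s=60.0))
            mp = psd.mean_power()
            mask = (psd.freqs >= 6) & (psd.freqs <= 14)
            fmax = psd.freqs[mask][np.argmax(mp[mask])]
            assert abs(fmax - iaf) <= 0.5

    def test_zero_posterior_gain_flattens_alpha_gradient(self):
        rec = rd.synthesize_background(128.0, 120.0, posterior_gain=0.0,
                                       seed=4)
        psd = rd.welch_psd(rec, rd.segment_epochs(rec, span_s=120.0))
        alpha = rd.band_power(psd, (8.0, 11.0))
        o1 = alpha[list(psd.labels).index("O1")]
        fp1 = alpha[list(psd.labels).index("Fp1")]
        assert abs(np.log10(o1) - np.log10(fp1)) < 0.12

    def test_posterior_gradient_present_by_default(self):
        rec = rd.synthesize_background(128.0, 60.0, seed=4)
        psd = rd.welch_psd(rec, rd.segment_epochs(rec, span_s=60.0))
        alpha = rd.band_power(psd, (8.0, 11.0))
        o1 = alpha[list(psd.labels).index("O1")]
        fp1 = alpha[list(psd.labels).index("Fp1")]
        assert o1 > 2.0 * fp1


class TestEpileptiformInjection:
    def test_rate_zero_is_identity(self, background_recording):
        rec, events = rd.inject_epileptiform(background_recording, rate=0.0)
        assert events == []
        assert np.array_equal(rec.data, background_recording.data)

    def test_kinds_follow_duration_ranges(self, background_recording):
        _, ev50 = rd.inject_epileptiform(background_recording, rate=3.0,
                                         duration_range_ms=(49.9, 50.1),
                                         seed=1)
        assert all(e["kind"] == "spike" for e in ev50)
        _, ev150 = rd.inject_epileptiform(background_recording, rate=3.0,
                                          duration_range_ms=(149.9, 150.1),
                                          seed=1)
        assert all(e["kind"] == "sharp_wave" for e in ev150)

    def test_event_bookkeeping_matches_modifications(self):
        rec = rd.synthesize_background(128.0, 60.0, seed=9)
        rec2, events = rd.inject_epileptiform(rec, rate=6.0, seed=10)
        diff = np.abs(rec2.data - rec.data).max(axis=0)
        changed = np.flatnonzero(diff > 1e-9)
        assert len(events) > 0
        for ev in events:
            lo = int(ev["onset_s"] * 128)
            assert diff[lo: lo + 10].max() > 0
        # every modified sample is inside some event's footprint (spike +
        # after-wave < 1 s)
        for idx in changed:
            assert any(0 <= idx / 128 - ev["onset_s"] < 1.0 for ev in events)

    def test_unknown_channel_rejected(self, background_recording):
        with pytest.raises(ConfigurationError):
            rd.inject_epileptiform(background_recording, rate=1.0,
                                   channels=("XX",))

    def test_duration_range_validated(self, background_recording):
        with pytest.raises(ConfigurationError):
            rd.inject_epileptiform(background_recording, rate=1.0,
                                   duration_range_ms=(10.0, 50.0))


class TestRhythmicDelta:
    def test_amplitudes_in_benign_range(self, background_recording):
        _, runs = rd.inject_rhythmic_delta(background_recording, rate=2.0,
                                           region="temporal", seed=2)
        assert len(runs) > 0
        for run in runs:
            assert 50.0 <= run["amplitude_uv"] <= 100.0
            assert set(run["channels"]) <= {"T3", "T4", "T5", "T6"}

    def test_rate_zero_identity(self, background_recording):
        rec, runs = rd.inject_rhythmic_delta(background_recording, rate=0.0)
        assert runs == []
        assert np.array_equal(rec.data, background_recording.data)

    def test_runs_only_signal_has_no_epileptiform_events(self):
        """Benign rhythmic delta contains no transient passing the spike
        rules: detection on a runs-only signal finds nothing."""
        quiet = rd.synthesize_background(128.0, 60.0, seed=2,
                                         alpha_power=0.0,
                                         background_power=0.05,
                                         delta_power=0.0, theta_power=0.0)
        rec, runs = rd.inject_rhythmic_delta(quiet, rate=2.0,
                                             region="temporal", seed=3)
        assert len(runs) > 0
        status = rd.detect_eea(rec)
        assert status.n_events == 0

    def test_bad_region_rejected(self, background_recording):
        with pytest.raises(ConfigurationError):
            rd.inject_rhythmic_delta(background_recording, rate=1.0,
                                     region="parietal")


class TestArtifactInjection:
    def test_muscle_psd_plateau(self):
        """Muscle epochs show elevated, non-declining high-band power."""
        fs = 128.0
        rec = rd.synthesize_background(fs, 30.0, seed=5)
        rec2, arts = rd.inject_artifacts(rec, kinds=("muscle",), rate=4.0,
                                         seed=6)
        from scipy import signal as sps
        art = next(a for a in arts if a["kind"] == "muscle")
        lo = int(art["onset_s"] * fs)
        hi = lo + int(art["duration_s"] * fs)
        seg = rec2.eeg_data()[:, lo:hi]
        f, p = sps.welch(seg, fs=fs, nperseg=min(seg.shape[1], 128))
        tail = (f >= 25)
        slope = np.polyfit(f[tail], np.log10(p[:, tail].mean(axis=0)), 1)[0]
        assert slope >= -0.002
        # clean background declines
        seg0 = rec.eeg_data()[:, lo:hi]
        f0, p0 = sps.welch(seg0, fs=fs, nperseg=min(seg0.shape[1], 128))
        slope0 = np.polyfit(f0[tail], np.log10(p0[:, tail].mean(axis=0)), 1)[0]
        assert slope0 < slope

    def test_rate_zero_identity(self, background_recording):
        rec, arts = rd.inject_artifacts(background_recording, rate=0.0)
        assert arts == []
        assert np.array_equal(rec.data, background_recording.data)

    def test_empty_kinds_rejected(self, background_recording):
        with pytest.raises(ConfigurationError):
            rd.inject_artifacts(background_recording, kinds=(), rate=1.0)

    def test_every_artifact_overlaps_a_flagged_epoch(self):
        fs = 128.0
        rec = rd.synthesize_background(fs, 60.0, seed=8)
        rec2, arts = rd.inject_artifacts(rec, rate=3.0, seed=9)
        eps = rd.detect_artifacts(rd.segment_epochs(rec2, span_s=60.0), rec2)
        for art in arts:
            lo, hi = art["onset_s"], art["onset_s"] + art["duration_s"]
            ov = [ep for ep in eps if ep.start / fs < hi and ep.stop / fs > lo]
            assert any(ep.label != "clean" for ep in ov)


class TestNullCalibration:
    def test_no_effect_means_nominal_rejection_rate(self):
        """With all group effects zero, a two-sample test on temporal delta
        power rejects at about the nominal alpha over 200 replicates."""
        fs, dur = 128.0, 16.0
        t_idx = [rd.CHANNELS_1020.index(c) for c in ("T3", "T4", "T5", "T6")]
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = rd.CohortConfig(n_per_group=(2, 5, 5), fs=fs,
                                  duration_s=dur, delta_effect_size=0.0,
                                  eea_event_rate=0.0, artifact_rate=0.0,
                                  tirda_rate=0.0, seed=20000 + rep)
            recs, meta, truth = rd.generate_cohort(cfg)
            vals = {"noADMCI-noEEA": [], "noADMCI-EEA": []}
            for rec in recs:
                g = truth.groups[rec.subject_id]
                if g == "Nold":
                    continue
                psd = rd.welch_psd(rec, rd.segment_epochs(rec, span_s=dur))
                delta = rd.band_power(psd, (2.0, 4.0))
                vals[g].append(np.log10(delta[t_idx].mean()))
            p = sst.ttest_ind(vals["noADMCI-EEA"],
                              vals["noADMCI-noEEA"]).pvalue
            rejections += p < 0.05
        # binomial 95% band around 0.05 with n=200
        assert 2 <= rejections <= 19, f"{rejections}/200 rejections"


class TestEffectMonotonicity:
    def test_delta_effect_increases_regional_difference(self, inverse_setup):
        """Mean temporal-delta regional-activity difference between the EEA
        and noEEA groups grows with delta_effect_size (3 grid points)."""
        space, _, inv = inverse_setup
        from tests.conftest import subject_regional

        def mean_diff(d, n_rep=15):
            diffs = []
            for rep in range(n_rep):
                cfg = rd.CohortConfig(n_per_group=(2, 3, 3), duration_s=24.0,
                                      delta_effect_size=d,
                                      eea_event_rate=0.0, artifact_rate=0.0,
                                      tirda_rate=0.0, seed=31000 + rep)
                recs, meta, truth = rd.generate_cohort(cfg)
                vals = {"noADMCI-noEEA": [], "noADMCI-EEA": []}
                for rec in recs:
                    g = truth.groups[rec.subject_id]
                    if g == "Nold":
                        continue
                    sub = subject_regional(rec, inv, space, span_s=24.0)
                    v = sub[(sub.band == "delta")
                            & (sub.roi == "temporal")].log10_value.iloc[0]
                    vals[g].append(v)
                diffs.append(np.mean(vals["noADMCI-EEA"])
                             - np.mean(vals["noADMCI-noEEA"]))
            return float(np.mean(diffs))

        d0, d1, d2 = (mean_diff(d) for d in (0.0, 0.75, 1.5))
        assert d0 < d1 < d2
        assert abs(d0) < 0.1
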