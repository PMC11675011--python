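"""Synthetic cohort generator: programmed structure must be recoverable."""

import numpy as np
import pytest

from socoh.behavior import CHAMBERS, ChamberGeometry, assign_chamber
from socoh.simulate import (CohortSpec, HUB_REGIONS, generate_cohort,
                            generate_cohort_data, generate_lfp,
                            generate_session, generate_track)
from socoh.spectral import GAMMA, SpectralParams, band_aggregate, \
    ms_coherence, welch_psd


class TestSpecValidation:
    def test_pref_normalised(self):
        s = CohortSpec(pref_sham=(2.0, 1.0, 1.0))
        assert np.isclose(sum(s.pref_sham), 1.0)

    @pytest.mark.parametrize("kw", [
        {"power_deficit": 0.0},
        {"power_deficit": 1.5},
        {"coupling_social_sham": 1.2},
        {"fs_hz": 100.0},
        {"pref_sham": (0.0, 0.0, 0.0)},
        {"coupled_regions": ("NotARegion",)},
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortSpec(**kw)


class TestTrack:
    def test_degenerate_pref_stays_in_social(self):
        spec = CohortSpec(session_s=90.0, seed=1)
        track, truth = generate_track(spec, "sham01", pref=(1.0, 0.0, 0.0))
        assert truth["dwell_s"]["social"] == pytest.approx(90.0)
        labels = assign_chamber(track, ChamberGeometry())
        assert (labels == "social").all()

    def test_uniform_pref_occupancy_within_5pct(self):
        spec = CohortSpec(session_s=1800.0, seed=42)
        _, truth = generate_track(spec, "sham01", pref=(1 / 3, 1 / 3, 1 / 3))
        for ch in CHAMBERS:
            assert truth["dwell_s"][ch] == pytest.approx(600.0, abs=30.0)

    def test_zero_total_pref_rejected(self):
        spec = CohortSpec(session_s=60.0)
        with pytest.raises(ValueError):
            generate_track(spec, "sham01", pref=(0.0, 0.0, 0.0))

    def test_reproducible_under_seed(self):
        spec = CohortSpec(session_s=120.0, seed=9)
        t1, _ = generate_track(spec, "sham02")
        t2, _ = generate_track(spec, "sham02")
        assert t1.equals(t2)

    def test_frame_count_and_likelihood(self, short_session_spec):
        track, _ = generate_track(short_session_spec, "tbi01")
        assert len(track) == int(120 * 20)
        assert track["likelihood"].median() > 0.99

    def test_scored_labels_match_ground_truth_exactly(self, short_session_spec):
        from socoh.behavior import filter_likelihood
        track, truth = generate_track(short_session_spec, "sham01")
        filt = filter_likelihood(track, 0.9)
        labels = assign_chamber(filt, ChamberGeometry())
        assert (labels == truth["labels"]).all()

    def test_dwell_seconds_sum_to_session(self, short_session_spec):
        _, truth = generate_track(short_session_spec, "tbi02")
        assert sum(truth["dwell_s"].values()) == pytest.approx(120.0)


class TestLFP:
    def _labels(self, spec, chamber="social"):
        return np.full(int(spec.session_s * spec.fps), chamber, dtype="<U9")

    def test_uncoupled_pair_coherence_at_estimator_floor(self):
        spec = CohortSpec(session_s=60.0, seed=5, coupling_social_sham=0.0,
                          coupling_baseline=0.0)
        vals = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            rec, _ = generate_lfp(spec, "sham01", self._labels(spec), rng=rng)
            i = spec.region_names.index("VMS")
            j = spec.region_names.index("Prl")
            f, coh = ms_coherence(rec.signal[i].astype(float),
                                  rec.signal[j].astype(float), spec.fs_hz)
            vals.append(band_aggregate(f, coh, GAMMA))
        # 60 s of 1-s windows at 80% overlap: floor well below 0.1
        assert np.mean(vals) < 0.05

    def test_strong_coupling_dominates_one_pair(self):
        spec = CohortSpec(session_s=60.0, seed=5, gamma_amp=4.0,
                          coupling_social_sham=1.0, coupling_baseline=1.0,
                          coupled_regions=("VMS", "Prl"))
        rec, _ = generate_lfp(spec, "sham01", self._labels(spec))
        sig = rec.signal.astype(float)
        i, j = spec.region_names.index("VMS"), spec.region_names.index("Prl")
        k = spec.region_names.index("CA1")
        f, coh = ms_coherence(sig[i], sig[j], spec.fs_hz)
        assert band_aggregate(f, coh, GAMMA) > 0.8
        f, coh0 = ms_coherence(sig[i], sig[k], spec.fs_hz)
        assert band_aggregate(f, coh0, GAMMA) < 0.2

    def test_no_deficit_and_same_stream_identical_power(self):
        spec = CohortSpec(session_s=30.0, seed=3, power_deficit=1.0,
                          coupling_social_sham=0.5, coupling_baseline=0.5)
        labels = self._labels(spec)
        rec_s, _ = generate_lfp(spec, "sham01", labels, group="sham",
                                rng=np.random.default_rng(77))
        rec_t, _ = generate_lfp(spec, "sham01", labels, group="tbi",
                                rng=np.random.default_rng(77))
        assert np.array_equal(rec_s.signal, rec_t.signal)

    def test_power_deficit_squares_into_band_power(self):
        spec = CohortSpec(session_s=120.0, seed=21, amp_jitter_sd=0.0)
        labels = self._labels(spec, "center")  # baseline coupling everywhere
        ratios = []
        for rep in range(4):
            rng_a = np.random.default_rng(500 + rep)
            rng_b = np.random.default_rng(900 + rep)
            rec_s, _ = generate_lfp(spec, "sham01", labels, "sham", rng_a)
            rec_t, _ = generate_lfp(spec, "tbi01", labels, "tbi", rng_b)
            osc = {}
            for tag, rec in (("s", rec_s), ("t", rec_t)):
                f, psd = welch_psd(rec.signal.astype(float), spec.fs_hz)
                gam = band_aggregate(f, psd, GAMMA).mean()
                # subtract the shared 1/f floor measured just outside the band
                floor_band = band_aggregate(
                    f, psd, type(GAMMA)("bg", 70.0, 110.0)).mean()
                osc[tag] = gam - floor_band
            ratios.append(osc["t"] / osc["s"])
        assert np.mean(ratios) == pytest.approx(spec.power_deficit ** 2,
                                                rel=0.10)

    def test_coherence_monotone_in_coupling(self):
        kappas = [0.0, 0.25, 0.5, 1.0]
        means = []
        for kap in kappas:
            vals = []
            for rep in range(3):
                spec = CohortSpec(session_s=45.0, seed=11,
                                  coupling_social_sham=kap,
                                  coupling_baseline=kap,
                                  coupled_regions=("VMS", "Prl"))
                rec, _ = generate_lfp(spec, "sham01", self._labels(spec),
                                      rng=np.random.default_rng(300 + rep))
                sig = rec.signal.astype(float)
                i = spec.region_names.index("VMS")
                j = spec.region_names.index("Prl")
                f, coh = ms_coherence(sig[i], sig[j], spec.fs_hz)
                vals.append(band_aggregate(f, coh, GAMMA))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(fs_hz=110.0)


class TestCohort:
    def test_file_counts(self, tiny_spec, tmp_path):
        manifest = generate_cohort(tiny_spec, tmp_path)
        assert len(list((tmp_path / "tracks").glob("*.csv"))) == 4
        assert len(list((tmp_path / "lfp").glob("*.h5"))) == 4
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "region_map.yaml").exists()
        assert len(manifest["animals"]) == 4

    def test_manifest_byte_identical_across_runs(self, tiny_spec, tmp_path):
        generate_cohort(tiny_spec, tmp_path / "a")
        generate_cohort(tiny_spec, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.json").read_bytes() == \
            (tmp_path / "b" / "manifest.json").read_bytes()

    def test_manifest_dwell_matches_behavior_scoring(self, tiny_spec, tmp_path):
        from socoh.behavior import (assign_chamber, filter_likelihood,
                                    occupancy_and_entries)
        from socoh.io import read_track_csv
        manifest = generate_cohort(tiny_spec, tmp_path)
        a = manifest["animals"][0]
        track = read_track_csv(tmp_path / a["track"])
        labels = assign_chamber(filter_likelihood(track, 0.9),
                                ChamberGeometry())
        time_s, _ = occupancy_and_entries(labels, tiny_spec.fps)
        want = manifest["ground_truth"]["dwell_s"][a["animal_id"]]
        for ch in CHAMBERS:
            assert time_s[ch] == pytest.approx(want[ch], abs=1e-9)

    def test_sessions_deterministic(self, tiny_spec):
        s1 = generate_session(tiny_spec, "tbi01", 2)
        s2 = generate_session(tiny_spec, "tbi01", 2)
        assert np.array_equal(s1["rec"].signal, s2["rec"].signal)
        assert s1["track"].equals(s2["track"])

    def test_cohort_ground_truth_fields(self, tiny_spec):
        sessions, truth = generate_cohort_data(tiny_spec)
        assert set(truth.dwell_s) == {s["animal_id"] for s in sessions}
        assert truth.kappa["sham"]["social"] == tiny_spec.coupling_social_sham
        assert truth.kappa["tbi"]["social"] == tiny_spec.coupling_baseline
        for amps in truth.gamma_amplitude.values():
            assert len(amps) == 32
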