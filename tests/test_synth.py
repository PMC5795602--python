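import numpy as np
import pytest

from cardiofuse import session_io, synth
from cardiofuse.types import ValidationError

FS = 100.0


class TestBeatTimes:
    def test_degenerate_variance_gives_metronome(self):
        hrv = synth.HRVModel(mean_rr=1000, sd_rr=0, rsa_depth=0)
        t = synth.sample_beat_times(10, hrv, 0)
        np.testing.assert_allclose(t, np.arange(10), atol=1e-12)

    def test_same_seed_same_beats(self):
        hrv = synth.HRVModel()
        a = synth.sample_beat_times(60, hrv, 42)
        b = synth.sample_beat_times(60, hrv, 42)
        np.testing.assert_array_equal(a, b)

    def test_mean_rr_recovered_over_long_run(self):
        hrv = synth.HRVModel(mean_rr=900, sd_rr=50, rsa_depth=0)
        t = synth.sample_beat_times(600, hrv, 3)
        rr = np.diff(t) * 1000
        se = 50 / np.sqrt(rr.size)
        assert abs(rr.mean() - 900) < 3 * se

    def test_nonpositive_rr_rejected(self):
        hrv = synth.HRVModel(mean_rr=400, sd_rr=500)
        with pytest.raises(ValidationError, match="non-positive RR"):
            synth.sample_beat_times(600, hrv, 0)


class TestRenderChannel:
    def test_noise_free_constant_rr_is_periodic(self, models):
        m = synth.ModalityModel("PPG", models["PPG"].base_template, noise_sd=0)
        beats = np.arange(0, 20, 0.8)
        ch = synth.render_channel(beats, m, FS, 20, 0)
        period = 80  # samples
        a = ch.samples[period : 20 * period]
        b = ch.samples[2 * period : 21 * period]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_mech_delay_shows_in_cross_correlation(self, models):
        # identical waveforms rendered with and without the mechanical
        # delay cross-correlate at exactly that delay
        beats = np.arange(0, 60, 0.8)
        now = synth.ModalityModel("PPG", models["PPG"].base_template,
                                  noise_sd=0)
        late = synth.ModalityModel("PPG", models["PPG"].base_template,
                                   noise_sd=0, mech_delay=0.2)
        a = synth.render_channel(beats, now, FS, 60, 0).samples
        b = synth.render_channel(beats, late, FS, 60, 0).samples
        a = a - a.mean()
        b = b - b.mean()
        xc = np.correlate(b, a, mode="full")
        lags = np.arange(-a.size + 1, a.size)
        sel = (lags >= 0) & (lags < 70)
        best = lags[sel][np.argmax(xc[sel])]
        assert abs(best / FS - 0.2) <= 0.02

    def test_noise_only_variance_matches_model(self):
        m = synth.ModalityModel("PPG", np.zeros(16), noise_sd=0.7)
        ch = synth.render_channel([], m, FS, 60, 5)
        assert ch.samples.var() == pytest.approx(0.49, rel=0.05)


class TestProtocol:
    def test_episode_table_structure(self):
        episodes, markers = synth.synth_protocol()
        assert len(episodes) == 18  # 2 x 60-s rest + 16 x 30-s maneuvers
        assert episodes[-1].t_end == pytest.approx(600.0)
        maneuvers = [e.maneuver for e in episodes[1:-1]]
        assert maneuvers == list(synth.MANEUVER_ORDER) * 2
        assert [e.amplitude_class for e in episodes[1:9]] == ["low"] * 8

    def test_head_torsion_leaves_thorax_still(self):
        episodes, markers = synth.synth_protocol()
        ht = next(e for e in episodes if e.maneuver == "HT")
        i0, i1 = int(ht.t_start * FS), int(ht.t_end * FS)
        for m in markers:
            if m.marker_id in (2, 3, 4, 6):
                assert np.all(m.x[i0:i1] == 0)
                assert np.all(m.y[i0:i1] == 0)
                assert np.all(m.z[i0:i1] == 0)

    def test_high_amplitude_shift_doubles_displacement(self):
        episodes, markers = synth.synth_protocol(amplitudes=(50, 100))
        tsl = [e for e in episodes if e.maneuver == "TSL"]
        m2 = next(m for m in markers if m.marker_id == 2)

        def peak(e):
            i0, i1 = int(e.t_start * FS), int(e.t_end * FS)
            return np.abs(m2.x[i0:i1]).max()

        assert peak(tsl[1]) == pytest.approx(2 * peak(tsl[0]), rel=1e-9)
        assert peak(tsl[1]) == pytest.approx(100.0, rel=1e-6)

    def test_rest_episodes_have_no_motion(self):
        episodes, markers = synth.synth_protocol()
        for e in episodes:
            if e.maneuver != "REST":
                continue
            i0, i1 = int(e.t_start * FS), int(e.t_end * FS)
            for m in markers:
                assert np.all(m.x[i0:i1] == m.x[i0])


class TestArtifacts:
    def test_zero_motion_is_identity(self, models):
        n = 3000
        ch = synth.render_channel(np.arange(0, 30, 0.9), models["PPG"], FS, 30, 0)
        markers = [
            synth.MarkerTrajectory(mid, np.zeros(n), np.zeros(n), np.zeros(n), FS)
            for mid in range(1, 8)
        ]
        out = synth.inject_artifacts(ch, markers, [], models["PPG"], 1)
        np.testing.assert_array_equal(out.samples, ch.samples)

    def test_stand_up_sit_down_saturates_episode(self, protocol_recording):
        rec = protocol_recording
        ss = next(e for e in rec.episodes if e.maneuver == "S/S")
        i0, i1 = int(ss.t_start * FS), int(ss.t_end * FS)
        for name in synth.ARTIFACT_COUPLED:
            w = rec.channels[name].samples[i0:i1]
            hi = rec.channels[name].samples.max()
            assert np.mean(w == hi) >= 0.90

    def test_doubling_gain_quadruples_disturbance_variance(self, models):
        episodes, markers = synth.synth_protocol()
        beats = np.arange(0, 600, 0.9)
        base = synth.render_channel(beats, models["PPG"], FS, 600, 0)
        tsl = next(e for e in episodes if e.maneuver == "TSL")
        i0 = int(tsl.t_start * FS)
        i1 = int((tsl.t_start + 8) * FS)

        def disturbance_var(gain):
            m = synth.ModalityModel(
                "PPG", models["PPG"].base_template, noise_sd=0.05,
                artifact_gain=gain, rail=(-1e9, 1e9),
            )
            out = synth.inject_artifacts(base, markers, [], m, 7)
            return np.var(out.samples[i0:i1] - base.samples[i0:i1])

        ratio = disturbance_var(0.02) / disturbance_var(0.01)
        assert ratio == pytest.approx(4.0, rel=0.15)


class TestGenerateSession:
    def test_quiet_session_beat_count(self):
        cfg = synth.SessionConfig(
            duration=600, protocol=False, hrv=synth.HRVModel(mean_rr=857)
        )
        rec = synth.generate_session(cfg, 0)
        assert len(rec.ref_beats) == pytest.approx(600 / 0.857, rel=0.03)

    def test_protocol_session_episodes_and_length(self, protocol_recording):
        assert len(protocol_recording.episodes) == 18
        assert protocol_recording.duration == pytest.approx(600.0)

    def test_same_seed_byte_identical_on_disk(self, tmp_path):
        cfg = synth.SessionConfig(duration=30, protocol=False)
        for i in (1, 2):
            session_io.write_session(
                synth.generate_session(cfg, 9), str(tmp_path / f"s{i}"), fmt="csv"
            )
        for name in ("header.json", "signals.csv", "beats.txt", "episodes.csv"):
            assert (tmp_path / "s1" / name).read_bytes() == (
                tmp_path / "s2" / name
            ).read_bytes()

    def test_cycle_onsets_coincide_with_annotations(self, models):
        # ground-truth consistency: rendered ECG cycles start at the beats
        hrv = synth.HRVModel(sd_rr=0, rsa_depth=0, mean_rr=900)
        cfg = synth.SessionConfig(duration=30, protocol=False, hrv=hrv)
        rec = synth.generate_session(cfg, 0)
        beats = rec.ref_beats.beat_samples
        np.testing.assert_allclose(np.diff(beats), 90, atol=1)
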