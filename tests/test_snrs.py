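import numpy as np
import pytest
from scipy import stats

from cardiofuse import snrs as S
from cardiofuse import synth
from cardiofuse.types import BeatAnnotations, SignalChannel, ValidationError

FS = 100.0


def periodic_signal(n_cycles=300, rr_s=0.9, template=None, noise_ratio=0.0, seed=0):
    """Noise-free periodic cardiac signal plus optional white noise at a
    given noise-to-signal power ratio; returns (channel, beats)."""
    rng = np.random.default_rng(seed)
    tmpl = synth.default_template("PPG", 512) if template is None else template
    beats = np.round(np.arange(n_cycles + 1) * rr_s * FS).astype(int)
    n = beats[-1] + 1
    sig = np.zeros(n)
    for b0, b1 in zip(beats[:-1], beats[1:]):
        phi = (np.arange(b0, b1) - b0) / (b1 - b0)
        sig[b0:b1] = np.interp(phi, np.arange(tmpl.size) / tmpl.size, tmpl)
    if noise_ratio > 0:
        sig = sig + rng.normal(0, np.sqrt(noise_ratio * np.mean(sig**2)), n)
    return SignalChannel("PPG", sig, FS), BeatAnnotations(beats)


class TestSegmentation:
    def test_cycles_between_consecutive_beats(self):
        ch = SignalChannel("PPG", np.arange(250, dtype=float), FS)
        ann = BeatAnnotations([0, 100, 200])
        cycles = S.segment_cycles(ch, ann, (0.0, 2.5))
        assert [len(c) for c in cycles] == [100, 100]
        np.testing.assert_array_equal(cycles[0], np.arange(100.0))

    def test_partial_leading_cycle_dropped(self):
        ch = SignalChannel("PPG", np.zeros(300), FS)
        ann = BeatAnnotations([0, 100, 200])
        cycles = S.segment_cycles(ch, ann, (0.5, 2.5))
        assert len(cycles) == 1  # only [100, 200) fully inside

    def test_single_beat_gives_empty(self):
        ch = SignalChannel("PPG", np.zeros(300), FS)
        cycles = S.segment_cycles(ch, BeatAnnotations([150]), (0.0, 3.0))
        assert cycles == []


class TestTemplate:
    def test_mean_of_identical_cycles(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 90, endpoint=False))
        tmpl = S.extract_template([c, c.copy(), c.copy()], p=180)
        expected = np.interp(np.arange(180) / 180, np.arange(90) / 90, c)
        np.testing.assert_allclose(tmpl.values, expected, atol=1e-12)
        assert tmpl.n_cycles_used == 3

    def test_opposite_cycles_cancel(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 80, endpoint=False))
        tmpl = S.extract_template([c, -c], p=160)
        np.testing.assert_allclose(tmpl.values, 0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            S.extract_template([], p=64)

    def test_recovery_from_noisy_cycles(self):
        # 300 cycles at per-sample SNR 10 dB: the averaged template
        # correlates > 0.99 with the generating waveform
        ch, ann = periodic_signal(n_cycles=300, noise_ratio=0.1, seed=1)
        cycles = S.segment_cycles(ch, ann, (0.0, ch.duration))
        tmpl = S.extract_template(cycles, p=200)
        truth = np.interp(
            np.arange(200) / 200,
            np.arange(512) / 512,
            synth.default_template("PPG", 512),
        )
        assert stats.pearsonr(tmpl.values, truth).statistic > 0.99


class TestApproximation:
    def test_self_approximation_of_periodic_signal(self):
        ch, ann = periodic_signal(n_cycles=50)
        win = (0.0, ch.duration)
        cycles = S.segment_cycles(ch, ann, win)
        # P at least 4x the samples per cycle
        tmpl = S.extract_template(cycles, p=512)
        est, inc = S.approximate_signal(tmpl, ann, win, FS, ch.n)
        x = ch.samples[: est.size]
        rms_err = np.sqrt(np.mean((est[inc] - x[inc]) ** 2))
        rms_sig = np.sqrt(np.mean(x[inc] ** 2))
        assert rms_err / rms_sig < 1e-3

    def test_constant_template_gives_constant_estimate(self):
        tmpl = S.CardiacTemplate(np.arange(64) / 64, np.full(64, 2.5), 1)
        ann = BeatAnnotations([0, 100, 200])
        est, inc = S.approximate_signal(tmpl, ann, (0.0, 2.0), FS, 300)
        assert np.all(est[inc] == 2.5)

    def test_cycle_lengths_track_rr(self):
        ann = BeatAnnotations([0, 80, 200, 290])
        tmpl = S.CardiacTemplate(np.arange(64) / 64, np.sin(np.arange(64)), 1)
        est, inc = S.approximate_signal(tmpl, ann, (0.0, 3.0), FS, 300)
        assert inc[:290].all() and not inc[290:].any()


class TestComputeSnrs:
    def test_exact_match_is_flagged_infinite(self):
        x = np.sin(np.arange(100) / 3.0)
        r = S.compute_snrs(x, x.copy())
        assert np.isinf(r.snrs_db) and r.degenerate == "zero_residual"

    def test_equal_powers_give_zero_db(self):
        est = np.array([1.0, -1.0] * 50)
        x = np.zeros(100)  # residual == estimate power
        r = S.compute_snrs(x, est)
        assert r.snrs_db == pytest.approx(0.0, abs=1e-12)

    def test_plug_in_ten_db(self):
        rng = np.random.default_rng(0)
        est = rng.standard_normal(10000)
        noise = rng.standard_normal(10000)
        noise *= np.sqrt(0.1 * np.sum(est**2) / np.sum(noise**2))
        r = S.compute_snrs(est + noise, est)
        assert r.snrs_db == pytest.approx(10.0, abs=1e-6)

    def test_zero_signal_is_flagged(self):
        r = S.compute_snrs(np.ones(10), np.zeros(10))
        assert r.snrs_db == -np.inf and r.degenerate == "zero_signal"


class TestInvariances:
    def snrs_of(self, ch, ann, p=200):
        win = (0.0, ch.duration)
        cycles = S.segment_cycles(ch, ann, win)
        tmpl = S.extract_template(cycles, p=p)
        est, inc = S.approximate_signal(tmpl, ann, win, FS, ch.n)
        return S.compute_snrs(ch.samples[: est.size], est, inc).snrs_db

    def test_oracle_recovery_at_ten_db(self):
        ch, ann = periodic_signal(n_cycles=300, noise_ratio=0.1, seed=0)
        assert self.snrs_of(ch, ann) == pytest.approx(10.0, abs=0.5)

    def test_amplitude_scale_invariance(self):
        ch, ann = periodic_signal(n_cycles=50, noise_ratio=0.2, seed=2)
        scaled = SignalChannel("PPG", 5.0 * ch.samples, FS)
        assert self.snrs_of(scaled, ann) == pytest.approx(self.snrs_of(ch, ann))

    def test_monotone_decrease_with_noise(self):
        vals = [
            self.snrs_of(*periodic_signal(n_cycles=100, noise_ratio=q, seed=4))
            for q in (0.02, 0.05, 0.1, 0.2, 0.5)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_template_idempotence(self):
        ch, ann = periodic_signal(n_cycles=60)
        win = (0.0, ch.duration)
        tmpl = S.extract_template(S.segment_cycles(ch, ann, win), p=512)
        est, _ = S.approximate_signal(tmpl, ann, win, FS, ch.n)
        re_ch = SignalChannel("PPG", est, FS)
        tmpl2 = S.extract_template(S.segment_cycles(re_ch, ann, win), p=512)
        np.testing.assert_allclose(tmpl2.values, tmpl.values, atol=5e-3)


class TestPerEpisode:
    def test_clean_session_rest_and_maneuver_agree(self, quiet_recording):
        rec = quiet_recording
        # carve pseudo-episodes out of the quiet session: with no
        # artifacts the maneuver and rest windows score alike
        from cardiofuse.types import ProtocolEpisode

        episodes = [
            ProtocolEpisode("TSL", "low", t, t + 30.0) for t in range(30, 270, 30)
        ]
        # cECG has no respiratory amplitude modulation, so the two
        # windows differ only by noise realization
        table = S.snrs_per_episode(rec, "cECG", episodes)
        diff = (table.snrs_maneuver_db - table.snrs_rest_db).abs()
        assert (diff < 1.0).all()

    def test_artifact_session_rest_beats_maneuver(self, protocol_recording):
        for modality in ("cECG", "PPG", "BCG_OPT", "BCG_EMFI"):
            table = S.snrs_per_episode(protocol_recording, modality)
            moving = table[~table.maneuver.isin(["HT", "LA", "RA"])]
            assert moving.snrs_rest_db.median() > moving.snrs_maneuver_db.median()

    def test_saturated_episode_skipped(self, protocol_recording):
        table = S.snrs_per_episode(protocol_recording, "PPG")
        assert "S/S" not in set(table.maneuver)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        import pandas as pd

        key = dict(maneuver="TSL", amplitude_class="low")
        snrs_t = pd.DataFrame(
            [{**key, "t_start": i, "snrs_maneuver_db": -2.0 * i} for i in range(5)]
        )
        mot_t = pd.DataFrame(
            [
                {**key, "t_start": i, "rms_x": float(i), "rms_y": 1.0, "rms_z": 0.0}
                for i in range(5)
            ]
        )
        rho = S.correlate_snrs_motion(snrs_t, mot_t)
        assert rho["x"] == pytest.approx(-1.0)
        assert np.isnan(rho["y"]) and np.isnan(rho["z"])  # zero variance

    def test_shuffled_pairing_decorrelates(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 16
        snrs_vals = -np.arange(n, dtype=float)
        rhos = []
        for _ in range(100):
            perm = rng.permutation(n)
            snrs_t = pd.DataFrame(
                {
                    "maneuver": ["TSL"] * n,
                    "amplitude_class": ["low"] * n,
                    "t_start": np.arange(n),
                    "snrs_maneuver_db": snrs_vals[perm],
                }
            )
            mot_t = pd.DataFrame(
                {
                    "maneuver": ["TSL"] * n,
                    "amplitude_class": ["low"] * n,
                    "t_start": np.arange(n),
                    "rms_x": np.arange(n, dtype=float),
                    "rms_y": np.arange(n, dtype=float),
                    "rms_z": np.arange(n, dtype=float),
                }
            )
            rhos.append(S.correlate_snrs_motion(snrs_t, mot_t)["x"])
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se + 0.05
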