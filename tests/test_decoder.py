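import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sig
from scipy import stats

from mubci import (ARModel, ChannelNotFoundError, DecoderConfig, EEGRecording,
                   ImageryClass, MuStreamGenerator, OnlineDecoder, RunningNorm,
                   ar_band_amplitude, condition, control_signal, fit_ar,
                   small_laplacian)
from conftest import welch_band_power

FS = 250.0
CFG = DecoderConfig(bandpass=(0.5, 100.0))


def _rec(data, labels=("C3",), fs=FS):
    return EEGRecording(np.atleast_2d(data), fs, labels)


class TestCondition:
    def test_notch_kills_60hz(self):
        # steady-state check: interior samples, away from the transient the
        # narrow notch necessarily rings at the signal edges
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        out = condition(_rec(x), CFG).data[0]
        mid = slice(int(2 * FS), int(6 * FS))
        assert np.sqrt(np.mean(out[mid] ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_passband_preserves_12hz(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 12.0 * t)
        out = condition(_rec(x), CFG).data[0]
        mid = slice(int(FS), int(3 * FS))
        assert out[mid].max() == pytest.approx(1.0, rel=0.02)

    def test_zero_in_zero_out(self):
        out = condition(_rec(np.zeros(1000)), CFG)
        assert np.allclose(out.data, 0.0)

    def test_rate_too_low(self):
        with pytest.raises(ValueError):
            condition(_rec(np.zeros(1000), fs=150.0), CFG)

    def test_length_preserved(self):
        out = condition(_rec(np.random.default_rng(0).normal(size=777)), CFG)
        assert out.n_samples == 777


class TestSmallLaplacian:
    LABELS = ("C3", "FC3", "CP3", "C1", "C5")

    def test_common_mode_rejection(self):
        x = np.random.default_rng(1).normal(size=500)
        rec = EEGRecording(np.tile(x, (5, 1)), FS, self.LABELS)
        assert np.allclose(small_laplacian(rec, "C3", CFG), 0.0)

    def test_identity_when_neighbors_silent(self):
        x = np.random.default_rng(2).normal(size=500)
        data = np.zeros((5, 500))
        data[0] = x
        rec = EEGRecording(data, FS, self.LABELS)
        assert np.allclose(small_laplacian(rec, "C3", CFG), x)

    def test_missing_channel_error(self):
        rec = EEGRecording(np.zeros((2, 10)), FS, ("C3", "FC3"))
        with pytest.raises(ChannelNotFoundError):
            small_laplacian(rec, "C3", CFG)

    def test_laplacian_improves_mu_snr(self, fast_params):
        # Welch-based SNR oracle: mu band power over broadband power
        def snr(x):
            band = welch_band_power(x, FS, (10, 14))
            broad = welch_band_power(x, FS, (1, 120))
            return band / broad

        wins = 0
        for seed in range(50):
            g = MuStreamGenerator(fast_params.with_seed(seed))
            rec = g.next_block(int(10 * FS))
            if snr(small_laplacian(rec, "C3", CFG)) > snr(rec.channel("C3")):
                wins += 1
        assert wins >= 45


class TestFitAR:
    def test_recovers_known_ar2(self):
        # oracle: the generating coefficients themselves
        w = np.array([1.3, -0.6])
        rng = np.random.default_rng(7)
        y = sig.lfilter([1.0], np.r_[1.0, -w], rng.standard_normal(10_000))
        model = fit_ar(y, 2)
        assert np.allclose(model.coefficients, w, atol=0.02)

    def test_white_noise_near_zero_coeffs(self):
        rng = np.random.default_rng(11)
        n = 5000
        model = fit_ar(rng.standard_normal(n), 8)
        assert np.all(np.abs(model.coefficients) < 3.0 / math.sqrt(n))

    def test_sinusoid_perfectly_predictable(self):
        t = np.arange(2000) / FS
        y = np.sin(2 * np.pi * 12.0 * t)
        model = fit_ar(y, 16)
        assert model.residual_variance / np.var(y) < 1e-3

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            fit_ar(np.zeros(10), 16)

    def test_constant_input_degenerate(self):
        model = fit_ar(np.full(100, 3.14), 4)
        assert model.degenerate
        assert np.allclose(model.coefficients, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_consistency_random_stable_ar(self, seed):
        # random stable AR(p<=16): coefficient error < 0.05 at 1e4 samples
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 8))
        roots = rng.uniform(0.3, 0.8, p) * np.exp(
            2j * np.pi * rng.uniform(0, 0.5, p))
        poly = np.real(np.poly(np.r_[roots, roots.conj()]))[: p + 1]
        poly = np.real(np.poly(roots[: p // 2].tolist()
                               + np.conj(roots[: p // 2]).tolist()))
        w_true = -poly[1:]
        y = sig.lfilter([1.0], poly, rng.standard_normal(10_000))
        model = fit_ar(y, len(w_true))
        assert np.max(np.abs(model.coefficients - w_true)) < 0.05


class TestARBandAmplitude:
    def test_band_contrast_for_in_band_sinusoid(self):
        t = np.arange(2000) / FS
        rng = np.random.default_rng(3)
        y = np.sin(2 * np.pi * 12.0 * t) + 0.05 * rng.standard_normal(len(t))
        model = fit_ar(y, 16)
        in_band = ar_band_amplitude(model, (10, 14), FS)
        out_band = ar_band_amplitude(model, (20, 24), FS)
        assert in_band >= 10 * out_band

    def test_white_noise_flat(self):
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            model = fit_ar(rng.standard_normal(1000), 16)
            ratios.append(ar_band_amplitude(model, (10, 14), FS)
                          / ar_band_amplitude(model, (30, 34), FS))
        assert all(0.5 <= r <= 2.0 for r in ratios)

    def test_invalid_band(self):
        model = ARModel(np.zeros(2), 2, 1.0)
        with pytest.raises(ValueError):
            ar_band_amplitude(model, (100, 200), FS)

    def test_erd_amplitude_ratio(self, fast_params, short_timing):
        # amplitude scales with (1 - erd_depth), not its square
        from mubci import generate_trial
        fs = fast_params.sampling_rate
        win = int(0.4 * fs)
        base_amps, feed_amps = [], []
        n_windows = 0
        seed = 0
        while n_windows < 200:
            rec, _ = generate_trial(ImageryClass.BOTH_HANDS, short_timing,
                                    fast_params.with_seed(seed))
            lap = small_laplacian(rec, "C3", CFG)
            for i in range(4):
                b = lap[i * win:(i + 1) * win]
                f = lap[int(6 * fs) + i * win:int(6 * fs) + (i + 1) * win]
                base_amps.append(ar_band_amplitude(fit_ar(b, 16), (10, 14), fs))
                feed_amps.append(ar_band_amplitude(fit_ar(f, 16), (10, 14), fs))
                n_windows += 2
            seed += 1
        assert np.mean(feed_amps) / np.mean(base_amps) == pytest.approx(0.5, rel=0.15)


class TestRunningNorm:
    def test_constant_input_degenerate_zero(self):
        norm = RunningNorm(halflife=2.0, update_interval=0.04)
        zs = [norm(5.0) for _ in range(100)]
        assert zs[-1] == 0.0
        assert norm.degenerate

    def test_unit_variance_calibration(self):
        rng = np.random.default_rng(0)
        norm = RunningNorm(halflife=4.0, update_interval=0.04)
        zs = np.array([norm(x) for x in rng.standard_normal(100_000)])
        assert 0.8 <= np.var(zs[1000:]) <= 1.2

    def test_step_response_halflife(self):
        # mean tracker covers half of a step change within ~one half-life
        h, dt = 2.0, 0.04
        norm = RunningNorm(halflife=h, update_interval=dt)
        rng = np.random.default_rng(1)
        for x in rng.normal(0.0, 0.1, size=20_000):
            norm(x)
        steps_to_half = None
        for k in range(10_000):
            norm(10.0 + rng.normal(0.0, 0.1))
            if norm.mean >= 5.0:
                steps_to_half = k + 1
                break
        assert steps_to_half is not None
        assert steps_to_half * dt == pytest.approx(h, rel=0.20)

    def test_no_update_freezes_stats(self):
        norm = RunningNorm(halflife=1.0, update_interval=0.04)
        rng = np.random.default_rng(2)
        for x in rng.standard_normal(1000):
            norm(x)
        mean = norm.mean
        norm(100.0, update=False)
        assert norm.mean == mean


class TestControlSignal:
    def test_rest_no_drift(self):
        assert control_signal(0.0, 0.0) == (0.0, 0.0)

    def test_right_hand_drives_rightward(self):
        # right-hand imagery: left-hemisphere ERD, left_z < 0 -> vx > 0
        vx, vy = control_signal(-1.0, 0.0)
        assert vx == pytest.approx(1.0)

    def test_both_hands_drives_up(self):
        vx, vy = control_signal(-1.0, -1.0)
        assert (vx, vy) == (0.0, pytest.approx(1.0))

    def test_relax_drives_down(self):
        vx, vy = control_signal(1.0, 1.0)
        assert vy == pytest.approx(-1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            control_signal(float("nan"), 0.0)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotonic_in_difference(self, left_z, right_z, delta):
        vx1, _ = control_signal(left_z, right_z)
        vx2, _ = control_signal(left_z, right_z + delta)
        assert vx2 > vx1

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_vy_decreasing_in_sum(self, left_z, right_z, delta):
        _, vy1 = control_signal(left_z, right_z)
        _, vy2 = control_signal(left_z + delta, right_z)
        assert vy2 < vy1


class TestOnlineDecoder:
    def test_rate_contract(self, fast_params):
        cfg = CFG
        fs = fast_params.sampling_rate
        dec = OnlineDecoder(cfg, fs, fast_params.channel_labels)
        g = MuStreamGenerator(fast_params)
        total = 0
        for n in (33, 100, 7, 260, 400):
            total += len(dec.process(g.next_block(n).data))
        expected = int(800 / (cfg.update_interval * fs))
        assert total == expected

    def test_warmup_flagged(self, fast_params):
        dec = OnlineDecoder(CFG, fast_params.sampling_rate,
                            fast_params.channel_labels)
        g = MuStreamGenerator(fast_params)
        states = dec.process(g.next_block(20).data)
        assert states and all(s.warmup for s in states)

    def test_rest_stream_centred(self, fast_params):
        cfg = dataclasses.replace(CFG, gain_x=1.0, gain_y=1.0,
                                  normalizer_halflife=10.0)
        fs = fast_params.sampling_rate
        dec = OnlineDecoder(cfg, fs, fast_params.channel_labels)
        g = MuStreamGenerator(fast_params.with_seed(42))
        vx, vy = [], []
        for _ in range(int(120.0 / cfg.update_interval)):
            for s in dec.process(g.next_block(int(cfg.update_interval * fs)).data):
                if not s.warmup:
                    vx.append(s.vx)
                    vy.append(s.vy)
        burn = len(vx) // 4
        assert abs(np.mean(vx[burn:])) < 0.1
        assert abs(np.mean(vy[burn:])) < 0.1

    def _imagery_run(self, fast_params, imagery, seed):
        cfg = dataclasses.replace(CFG, gain_x=1.0, gain_y=1.0,
                                  normalizer_halflife=15.0)
        fs = fast_params.sampling_rate
        block = int(cfg.update_interval * fs)
        dec = OnlineDecoder(cfg, fs, fast_params.channel_labels)
        g = MuStreamGenerator(fast_params.with_seed(seed))
        for _ in range(int(10.0 / cfg.update_interval)):  # REST warm-up
            dec.process(g.next_block(block).data)
        g.set_imagery(imagery)
        vx, vy = [], []
        skip = int((1.0 + fast_params.modulation_latency) / cfg.update_interval)
        for k in range(int(5.0 / cfg.update_interval)):
            for s in dec.process(g.next_block(block).data):
                if k >= skip:
                    vx.append(s.vx)
                    vy.append(s.vy)
        return np.mean(vx), np.mean(vy)

    def test_right_hand_stream_positive_vx(self, fast_params):
        means = [self._imagery_run(fast_params, ImageryClass.RIGHT_HAND, s)[0]
                 for s in range(50)]
        assert stats.ttest_1samp(means, 0.0, alternative="greater").pvalue < 0.01

    def test_relax_stream_negative_vy(self, fast_params):
        p = dataclasses.replace(fast_params, ers_gain=0.3)
        means = [self._imagery_run(p, ImageryClass.RELAX, s)[1]
                 for s in range(50)]
        assert stats.ttest_1samp(means, 0.0, alternative="less").pvalue < 0.01

    def test_normalizer_absorbs_amplitude_scale(self, fast_params):
        # doubling mu amplitude leaves post-warm-up z features unchanged
        def z_stats(params):
            cfg = CFG
            fs = params.sampling_rate
            dec = OnlineDecoder(cfg, fs, params.channel_labels)
            g = MuStreamGenerator(params)
            zs = []
            for _ in range(int(60.0 / cfg.update_interval)):
                for s in dec.process(g.next_block(int(cfg.update_interval * fs)).data):
                    if not s.warmup:
                        zs.append(s.left_z)
            burn = len(zs) // 3
            return np.mean(zs[burn:]), np.std(zs[burn:])

        m1, s1 = z_stats(fast_params.with_seed(5))
        m2, s2 = z_stats(dataclasses.replace(fast_params, mu_baseline_amp=20.0,
                                             seed=5))
        assert abs(m1 - m2) < 0.2
        assert abs(s1 - s2) < 0.3


class TestConfigValidation:
    def test_band_order(self):
        with pytest.raises(ValueError):
            DecoderConfig(band_low=14, band_high=10)

    def test_update_interval_bound(self):
        with pytest.raises(ValueError):
            DecoderConfig(update_interval=1.0, window_length=0.4)

    def test_ar_order_vs_window(self):
        cfg = DecoderConfig(bandpass=(0.5, 100.0), ar_order=200)
        with pytest.raises(ValueError):
            cfg.validate_rate(250.0)
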