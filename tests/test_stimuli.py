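"""Stimulus and synthetic-behavior generator tests."""

import numpy as np
import pytest

from noiseschema.frontend import design_filterbank, compute_cochleagram, excitation_pattern
from noiseschema.stimuli import (
    ExperimentDesign,
    ForegroundSpec,
    TextureSpec,
    TrialSpec,
    build_trial_set,
    experiment_design,
    gen_foreground,
    gen_spectrally_matched_noise,
    gen_synthetic_behavior,
    gen_texture_background,
    insert_interrupter,
    mix_at_snr,
)

SR = 20_000.0


class TestTextureBackground:
    def test_deterministic_in_seed(self):
        spec = TextureSpec(seed=42)
        w1, w2 = gen_texture_background(spec), gen_texture_background(spec)
        assert np.array_equal(w1.samples, w2.samples)

    def test_seeds_differ_but_spectra_match(self):
        spec = TextureSpec(seed=1, mod_depth=0.5)
        fb = design_filterbank(20, 50, 8000, SR)
        exs = []
        for seed in (1, 2):
            w = gen_texture_background(TextureSpec(seed=seed, mod_depth=0.5))
            exs.append(excitation_pattern(compute_cochleagram(w, fb)))
        w1 = gen_texture_background(TextureSpec(seed=1, mod_depth=0.5))
        w2 = gen_texture_background(TextureSpec(seed=2, mod_depth=0.5))
        assert not np.array_equal(w1.samples, w2.samples)
        assert np.allclose(exs[0], exs[1], rtol=0.12)

    def test_mod_depth_zero_is_stationary_noise(self):
        from noiseschema.metrics import nonstationarity

        w0 = gen_texture_background(TextureSpec(seed=5, mod_depth=0.0))
        w9 = gen_texture_background(TextureSpec(seed=5, mod_depth=0.9))
        n0 = nonstationarity(w0, normalizer=None, n_reference=10).value
        n9 = nonstationarity(w9, normalizer=None, n_reference=10).value
        assert n9 > n0

    def test_duration_and_rms(self):
        w = gen_texture_background(TextureSpec(seed=0, duration=1.5))
        assert len(w.samples) == int(1.5 * SR)
        assert w.rms == pytest.approx(0.05, rel=1e-6)


class TestSpectrallyMatchedNoise:
    def test_magnitude_spectrum_and_rms_preserved(self):
        src = gen_texture_background(TextureSpec(seed=3))
        out = gen_spectrally_matched_noise(src, seed=9)
        assert out.rms == pytest.approx(src.rms, rel=1e-9)
        m1 = np.abs(np.fft.rfft(src.samples))
        m2 = np.abs(np.fft.rfft(out.samples))
        # identical magnitudes up to the overall RMS rescale
        assert np.allclose(m2[1:-1] / m1[1:-1], m2[1] / m1[1], rtol=1e-6)

    def test_more_stationary_than_modulated_source(self):
        from noiseschema.metrics import nonstationarity

        src = gen_texture_background(TextureSpec(seed=8, mod_depth=0.8))
        out = gen_spectrally_matched_noise(src, seed=1)
        assert (nonstationarity(out, n_reference=10).value
                < nonstationarity(src, n_reference=10).value)


class TestForeground:
    def test_sample_count(self):
        w = gen_foreground(ForegroundSpec(seed=0))
        assert len(w.samples) == 10_000

    @pytest.mark.parametrize("kind", ["noise_burst", "chirp", "harmonic"])
    def test_kinds_generate_and_are_deterministic(self, kind):
        spec = ForegroundSpec(seed=4, kind=kind)
        w1, w2 = gen_foreground(spec), gen_foreground(spec)
        assert np.array_equal(w1.samples, w2.samples)
        assert w1.rms == pytest.approx(0.05, rel=1e-6)

    def test_harmonic_periodicity_exceeds_burst(self):
        from noiseschema.metrics import periodicity

        ph = periodicity(gen_foreground(ForegroundSpec(seed=1, kind="harmonic", f0=200)))
        pn = periodicity(gen_foreground(ForegroundSpec(seed=1, kind="noise_burst")))
        assert ph > 0.9 and pn < 0.3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ForegroundSpec(seed=0, kind="harmonic", f0=-1)
        with pytest.raises(ValueError):
            ForegroundSpec(seed=0, kind="whistle")


class TestMixing:
    def setup_method(self):
        self.bg = gen_texture_background(TextureSpec(seed=2))
        self.fg = gen_foreground(ForegroundSpec(seed=2))

    def test_zero_snr_matches_background_rms_over_extent(self):
        mix = mix_at_snr(self.fg, self.bg, 0.0, 1000)
        i0, i1 = 20_000, 30_000
        fg_part = mix.samples[i0:i1] - self.bg.samples[i0:i1]
        rms_bg = np.sqrt(np.mean(self.bg.samples[i0:i1] ** 2))
        assert np.sqrt(np.mean(fg_part**2)) == pytest.approx(rms_bg, rel=1e-9)

    def test_minus_six_db_is_quarter_power(self):
        mix = mix_at_snr(self.fg, self.bg, -6.02, 1000)
        i0, i1 = 20_000, 30_000
        fg_part = mix.samples[i0:i1] - self.bg.samples[i0:i1]
        ratio = np.mean(fg_part**2) / np.mean(self.bg.samples[i0:i1] ** 2)
        assert ratio == pytest.approx(0.25, rel=1e-3)

    def test_background_untouched_outside_extent(self):
        mix = mix_at_snr(self.fg, self.bg, -3.0, 1000)
        assert np.array_equal(mix.samples[:20_000], self.bg.samples[:20_000])
        assert np.array_equal(mix.samples[30_000:], self.bg.samples[30_000:])

    def test_overrun_and_early_onset_rejected(self):
        with pytest.raises(ValueError):
            mix_at_snr(self.fg, self.bg, 0.0, 3000)
        with pytest.raises(ValueError):
            mix_at_snr(self.fg, self.bg, 0.0, 100)


class TestInterrupter:
    def test_silence_zeroes_middle(self):
        bg = gen_texture_background(TextureSpec(seed=6))
        out = insert_interrupter(bg, "silence", 500)
        n, m = len(bg.samples), 10_000
        i0 = (n - m) // 2
        assert np.all(out.samples[i0 : i0 + m] == 0)
        assert np.array_equal(out.samples[:i0], bg.samples[:i0])
        assert len(out.samples) == n

    def test_white_noise_rms_matched_flat_spectrum(self):
        bg = gen_texture_background(TextureSpec(seed=6))
        out = insert_interrupter(bg, "white_noise", 1500, seed=3)
        n, m = len(bg.samples), 30_000
        i0 = (n - m) // 2
        seg = out.samples[i0 : i0 + m]
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(bg.rms, rel=1e-9)
        # flat spectrum: power in low vs high half of the band comparable
        p = np.abs(np.fft.rfft(seg)) ** 2
        half = len(p) // 2
        assert 0.7 < p[10:half].mean() / p[half:-10].mean() < 1.4

    def test_zero_duration_identity_and_too_long_rejected(self):
        bg = gen_texture_background(TextureSpec(seed=6, duration=1.0))
        out = insert_interrupter(bg, "silence", 0)
        assert np.array_equal(out.samples, bg.samples)
        with pytest.raises(ValueError):
            insert_interrupter(bg, "silence", 1000)


class TestTrialSets:
    def test_exp1_balance_and_background_only(self):
        design = experiment_design("exp1", n_backgrounds=20)
        trials = build_trial_set(design, master_seed=0)
        fg = [s for _, s in trials if s.foreground_id is not None]
        bg = [s for _, s in trials if s.foreground_id is None]
        assert len(fg) == 20 and len(bg) == 20
        conds = {(s.onset_ms, s.snr_db) for s in fg}
        assert len(conds) == 20  # 10 onsets x 2 SNRs, exactly one each

    def test_deterministic_under_master_seed(self):
        design = experiment_design("exp1", n_backgrounds=20,
                                   onsets_ms=(250, 500), snrs_db=(-2.0,))
        t1 = build_trial_set(design, master_seed=5)
        t2 = build_trial_set(design, master_seed=5)
        assert all(np.array_equal(a.samples, b.samples)
                   for (a, _), (b, _) in zip(t1, t2))

    def test_exp8_alternating_repeat_flags(self):
        design = experiment_design("exp8", n_backgrounds=16, block_size=8,
                                   onsets_ms=(250, 500, 750, 1000))
        trials = build_trial_set(design, master_seed=1)
        specs = [s for _, s in trials]
        for i, s in enumerate(specs):
            k = i % 8
            assert s.repeat == (k % 2 == 0)

    def test_unknown_design_and_imbalance_rejected(self):
        with pytest.raises(ValueError):
            experiment_design("exp99")
        with pytest.raises(ValueError, match="divisible"):
            build_trial_set(experiment_design("exp1", n_backgrounds=13), 0)

    def test_exp5_interrupter_present_in_all_trials(self):
        design = experiment_design("exp5a", n_backgrounds=8,
                                   onsets_ms=(250, 500), snrs_db=(-2.0,))
        trials = build_trial_set(design, master_seed=0)
        kinds = {s.interrupter for _, s in trials}
        assert kinds == {"silence", "white_noise"}
        # silence interrupter visible in the waveform middle
        for w, s in trials:
            if s.interrupter == "silence" and s.foreground_id is None:
                n, m = len(w.samples), 10_000
                i0 = (n - m) // 2
                assert np.all(w.samples[i0 + 100 : i0 + m - 100] == 0)
                break


class TestSyntheticBehavior:
    def test_null_observer_hit_rate_equals_false_alarm_rate(self):
        tb = gen_synthetic_behavior({-2.0: (0.0, 0.0, 900.0)}, 40, 8, 160,
                                    seed=0, participant_sd=0.0)
        hit = tb[tb.foreground_present]["response"].mean()
        fa = tb[~tb.foreground_present]["response"].mean()
        # both are estimates of Phi(-criterion); allow 3 binomial SEs
        se = np.sqrt(0.16 * 0.84 * (1 / 3200 + 1 / 6400))
        assert abs(hit - fa) < 3 * se

    def test_fixed_seed_reproducible(self):
        args = ({-2.0: (0.5, 0.001, 900.0)}, 5, 4, 10)
        t1 = gen_synthetic_behavior(*args, seed=7)
        t2 = gen_synthetic_behavior(*args, seed=7)
        assert t1.to_csv() == t2.to_csv()

    def test_large_n_recovers_generating_curve(self):
        from noiseschema.psychophysics import dprime_by_onset
        from noiseschema.stimuli import elbow_curve

        params = (0.4, 0.0012, 900.0)
        tb = gen_synthetic_behavior({-2.0: params}, 120, 30, 400, seed=3,
                                    participant_sd=0.0)
        onsets, mat = dprime_by_onset(tb)
        truth = elbow_curve(onsets, *params)
        assert np.allclose(mat.mean(axis=0), truth, atol=0.12)

    def test_repeat_design_shares_spec_not_samples(self):
        design = experiment_design("exp6", n_backgrounds=8, block_size=8,
                                   onsets_ms=(250, 500, 750, 1000))
        trials = build_trial_set(design, master_seed=2)
        waves = [w for w, s in trials if s.repeat and s.foreground_id is None]
        assert len(waves) >= 2
        assert not np.array_equal(waves[0].samples, waves[1].samples)
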