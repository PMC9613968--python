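import numpy as np
import pytest

from gaitcomplexity import (
    GaitGenConfig,
    average_mutual_information,
    composite_multiscale_entropy,
    delay_embed,
    dominant_period,
    generate_benchmark,
    generate_gait,
    gfnn,
    joint_nld_summary,
    lyapunov_rosenstein,
    sample_entropy,
)
from _oracles import sample_entropy_bruteforce


class TestAMI:
    def test_sine_quarter_period_delay(self):
        x = generate_benchmark("sine", 6000, {"period": 60})
        curve = average_mutual_information(x, max_lag=40)
        assert abs(curve.selected_delay - 15) <= 1
        assert not curve.fallback_used

    def test_white_noise_falls_back(self):
        x = generate_benchmark("white", 6000, seed=5)
        curve = average_mutual_information(x, max_lag=40)
        assert curve.fallback_used
        assert np.all(curve.ami[1:] < 0.1)

    def test_periodic_dependence_identity(self):
        x = generate_benchmark("sine", 6000, {"period": 60})
        curve = average_mutual_information(x, max_lag=60)
        assert curve.ami[60] == pytest.approx(curve.ami[0], rel=1e-6)
        assert curve.ami[0] == curve.ami.max()

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero-entropy"):
            average_mutual_information(np.ones(1000), max_lag=10)

    def test_amplitude_invariance(self):
        x = generate_benchmark("sine", 4000, {"period": 50}) + 0.05 * generate_benchmark(
            "white", 4000, seed=2
        )
        d1 = average_mutual_information(x, max_lag=40).selected_delay
        d2 = average_mutual_information(7.3 * x, max_lag=40).selected_delay
        assert d1 == d2


class TestGFNN:
    def test_lorenz_embeds_by_three(self, lorenz_series):
        delay = average_mutual_information(lorenz_series, max_lag=200).selected_delay
        curve = gfnn(lorenz_series, delay=delay, max_dim=6)
        assert curve.fnn_fraction[0] > curve.threshold  # 1-D is badly folded
        assert curve.selected_dim <= 3
        assert curve.fnn_fraction[2] < 0.01  # essentially no false neighbors at 3
        assert not curve.saturated

    def test_sine_embeds_in_plane(self):
        x = generate_benchmark("sine", 6000, {"period": 60})
        assert gfnn(x, delay=15, max_dim=5).selected_dim <= 2

    def test_noise_saturates(self):
        x = generate_benchmark("white", 6000, seed=5)
        curve = gfnn(x, delay=1, max_dim=8)
        assert curve.saturated and curve.selected_dim == 8
        assert np.all(curve.fnn_fraction > curve.threshold)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            gfnn(np.sin(np.arange(30)), delay=5, max_dim=10)


class TestDelayEmbed:
    def test_definition(self):
        x = np.arange(1, 11, dtype=float)
        traj = delay_embed(x, delay=3, dim=2)
        assert traj.shape == (7, 2)
        np.testing.assert_array_equal(traj[0], [1, 4])

    def test_dim_one_identity(self):
        x = np.arange(10, dtype=float)
        np.testing.assert_array_equal(delay_embed(x, 1, 1).ravel(), x)

    def test_index_arithmetic(self):
        x = np.arange(10, dtype=float)
        traj = delay_embed(x, delay=2, dim=3)
        assert traj.shape == (6, 3)
        np.testing.assert_array_equal(traj[-1], [x[5], x[7], x[9]])

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            delay_embed(np.arange(5, dtype=float), delay=3, dim=3)


class TestLyapunov:
    def test_logistic_map_ln2(self, logistic_series):
        traj = delay_embed(logistic_series, 1, 1)
        res = lyapunov_rosenstein(traj, fs=1.0, mean_period=10, theiler=5, fit_window=(0, 6))
        assert res.lye == pytest.approx(np.log(2), rel=0.05)

    def test_sine_near_zero(self):
        x = generate_benchmark("sine", 10000, {"period": 60})
        traj = delay_embed(x, 15, 2)
        res = lyapunov_rosenstein(traj, fs=1.0, mean_period=60)
        assert abs(res.lye) < 0.05 * np.log(2)

    def test_lorenz_against_benettin_oracle(self, lorenz_series):
        from _oracles import lorenz_lyapunov_benettin

        reference = lorenz_lyapunov_benettin()
        assert reference == pytest.approx(0.9, abs=0.1)  # sanity: known regime
        delay = average_mutual_information(lorenz_series, max_lag=200).selected_delay
        traj = delay_embed(lorenz_series, delay, 3)
        res = lyapunov_rosenstein(
            traj, fs=100.0, mean_period=75, fit_window=(100, 300), max_steps=300
        )
        assert res.lye == pytest.approx(reference, rel=0.15)

    def test_fit_window_outside_curve(self, logistic_series):
        traj = delay_embed(logistic_series[:2000], 1, 1)
        with pytest.raises(ValueError, match="fit window"):
            lyapunov_rosenstein(
                traj, fs=1.0, mean_period=10, max_steps=20, fit_window=(10, 500)
            )


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(100, 3.0), m=2, r_abs=0.5) == 0.0

    def test_gaussian_closed_form(self):
        from scipy.special import erf

        rng = np.random.default_rng(3)
        x = rng.standard_normal(10000)
        se = sample_entropy(x, m=2, r_abs=0.2 * x.std())
        assert se == pytest.approx(-np.log(erf(0.1)), rel=0.05)

    def test_fast_equals_bruteforce(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            x = rng.standard_normal(60)
            r = 0.2 * x.std()
            fast = sample_entropy(x, m=2, r_abs=r)
            slow = sample_entropy_bruteforce(x, m=2, r=r)
            assert fast == slow or (np.isnan(fast) and np.isnan(slow))

    def test_no_matches_returns_nan(self):
        x = np.arange(50, dtype=float) ** 2
        assert np.isnan(sample_entropy(x, m=2, r_abs=1e-12 + 0.0001))

    def test_amplitude_invariance_with_relative_r(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(2000)
        a = sample_entropy(x, m=2, r_abs=0.2 * x.std())
        y = 5.0 * x
        b = sample_entropy(y, m=2, r_abs=0.2 * y.std())
        assert a == pytest.approx(b, rel=1e-12)


class TestCMSE:
    def test_scale_one_equals_sampen(self):
        x = generate_benchmark("white", 3000, seed=11)
        prof = composite_multiscale_entropy(x, n_scales=5)
        assert prof.cmse[0] == sample_entropy(x, m=2, r_abs=prof.r)

    def test_ci_additive_over_scales(self):
        x = generate_benchmark("white", 3000, seed=11)
        prof = composite_multiscale_entropy(x, n_scales=10)
        assert prof.ci == prof.cmse.sum()
        assert prof.ci_defined

    def test_white_noise_decreasing_profile(self):
        from scipy.stats import spearmanr

        x = generate_benchmark("white", 5000, seed=11)
        prof = composite_multiscale_entropy(x)
        assert spearmanr(prof.scales, prof.cmse).statistic < 0

    def test_pink_noise_flatter_and_higher_ci(self):
        white = composite_multiscale_entropy(generate_benchmark("white", 5000, seed=11))
        pink = composite_multiscale_entropy(generate_benchmark("pink", 5000, seed=11))
        assert pink.ci > white.ci
        # flatness: pink's profile decays far less from scale 1 to 20
        drop_white = white.cmse[0] - white.cmse[-1]
        drop_pink = pink.cmse[0] - pink.cmse[-1]
        assert abs(drop_pink) < 0.5 * drop_white

    def test_undefined_scale_flagged_never_infinite(self):
        x = np.random.default_rng(0).normal(size=300)
        # tolerance far below the spacing of values: no template matches
        prof = composite_multiscale_entropy(x, r_factor=1e-12, n_scales=3)
        assert not prof.ci_defined and np.isnan(prof.ci)
        assert not np.isinf(prof.cmse[np.isfinite(prof.cmse)]).any()


class TestJointSummary:
    def test_periodic_gait_low_lye_and_ci(self):
        cfg = GaitGenConfig(
            seed=31, n_strides=60, latent_rank=3, cycle_noise_sd=0.3,
            sensor_noise_sd=0.1, stride_duration_cv=0.0,
        )
        trial, _, _ = generate_gait(cfg)
        out = joint_nld_summary(trial, joints=["knee_L_sagittal"])
        res = out["knee_L_sagittal"]
        assert abs(res.lye.lye) < 2.0  # near-periodic: small per-second exponent
        assert res.cmse.ci < 10.0

    def test_chaotic_timing_raises_lye(self):
        def mean_lye(chaos, seed):
            cfg = GaitGenConfig(
                seed=seed, n_strides=60, latent_rank=3, cycle_noise_sd=0.5,
                sensor_noise_sd=0.2, chaos_mod=chaos, stride_duration_cv=0.0,
            )
            trial, _, _ = generate_gait(cfg)
            out = joint_nld_summary(trial)
            return np.mean([r.lye.lye for r in out.values()])

        for seed in (3, 4):
            assert mean_lye(0.12, seed) > mean_lye(0.0, seed)

    def test_short_trial_guard(self):
        trial, _, _ = generate_gait(GaitGenConfig(seed=2, n_strides=5))
        with pytest.raises(ValueError, match="nonlinear measures need"):
            joint_nld_summary(trial)

    def test_missing_channel_lists_sagittal(self):
        trial, _, _ = generate_gait(GaitGenConfig(seed=2, n_strides=20))
        with pytest.raises(KeyError, match="sagittal channels available"):
            joint_nld_summary(trial, joints=["knee_L_coronal"])


def test_dominant_period_of_sine():
    x = generate_benchmark("sine", 6000, {"period": 60})
    assert dominant_period(x) == pytest.approx(60, rel=0.01)
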