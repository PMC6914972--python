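"""Estimator correctness: DFA, low-frequency PSD, Whittle ARFIMA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalbench.estimation import (
    DFA,
    DFAConfig,
    LowPSD,
    WhittleARFIMA,
    arfima_estimate,
    dfa_estimate,
    dfa_fluctuation,
    dfa_profile,
    evenly_spaced_bins,
    periodogram,
    psd_estimate,
    psd_preprocess,
    whittle_objective,
)
from fractalbench.generators import (
    RandomStreams,
    Series,
    arfima_fgn,
    davies_harte_fgn,
    integrate_series,
)
from fractalbench.theory import SignalClass


class TestDfaProfile:
    def test_worked_example(self):
        # deviations from the mean are [-1, 0, 1, 0]; the profile accumulates
        assert np.allclose(dfa_profile([1.0, 2, 3, 2]), [-1, -1, 0, 0])

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(64)
        mean = sum(x) / len(x)
        oracle, acc = [], 0.0
        for v in x:
            acc += v - mean
            oracle.append(acc)
        assert np.allclose(dfa_profile(x), oracle, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=100))
    def test_profile_telescopes_to_zero(self, values):
        profile = dfa_profile(np.asarray(values))
        scale = max(1.0, np.max(np.abs(values)))
        assert abs(profile[-1]) < 1e-9 * len(values) * scale


class TestDfaFluctuation:
    def test_linear_profile_detrends_exactly(self):
        profile = 3.0 * np.arange(32) + 1.0
        assert dfa_fluctuation(profile, 8) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_window_oracle(self):
        # alternating profile, N=16, n=4: per-window OLS residual RMS by hand
        profile = np.array([0.0, 1, 0, 1] * 4)
        ss = 0.0
        for w in range(4):
            seg = profile[4 * w: 4 * w + 4]
            t = np.arange(4.0)
            slope, intercept = np.polyfit(t, seg, 1)
            ss += float(np.sum((seg - (slope * t + intercept)) ** 2))
        assert dfa_fluctuation(profile, 4) == pytest.approx(math.sqrt(ss / 16))

    def test_window_size_bounds(self):
        with pytest.raises(ValueError):
            dfa_fluctuation(np.zeros(32), 3)
        with pytest.raises(ValueError):
            dfa_fluctuation(np.zeros(32), 17)


class TestEvenlySpacedBins:
    def test_default_edges(self):
        edges = evenly_spaced_bins(DFAConfig())
        assert edges.size == 19
        assert edges[0] == pytest.approx(1.0)  # log10(10)
        widths = np.diff(edges)
        assert np.allclose(widths, math.log10(51.2) / 18)
        assert edges[-1] == pytest.approx(math.log10(512))

    def test_single_bin(self):
        edges = evenly_spaced_bins(DFAConfig(10, 100, 1))
        assert np.allclose(edges, [1.0, 2.0])

    def test_every_window_size_in_exactly_one_bin(self):
        cfg = DFAConfig()
        edges = evenly_spaced_bins(cfg)
        for n in range(10, 513):
            ln = math.log10(n)
            hits = [
                p for p in range(cfg.n_bins)
                if (edges[p] <= ln < edges[p + 1])
                or (p == cfg.n_bins - 1 and ln == edges[-1])
            ]
            assert len(hits) == 1


class TestDfaEstimator:
    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            dfa_estimate(Series(np.ones(1024)))

    def test_explicit_config_validated_against_length(self):
        x = Series(np.random.default_rng(0).standard_normal(256))
        with pytest.raises(ValueError):
            DFA(n_max=512).fit(x)
        # the adaptive default caps n_max at N/2 instead
        assert np.isfinite(DFA().fit(x).alpha_)

    def test_recovery_on_exact_fgn(self):
        # |mean alpha_hat - alpha| <= 0.05 on exact fGn
        for alpha in (0.1, 0.5, 0.9):
            est = [
                dfa_estimate(davies_harte_fgn(alpha, 1024, RandomStreams(100 + r))).alpha_hat
                for r in range(30)
            ]
            assert abs(np.mean(est) - alpha) <= 0.05

    def test_random_walk_scaling_and_variability_growth(self):
        walks, noises = [], []
        for r in range(40):
            wn = davies_harte_fgn(0.5, 1024, RandomStreams(700 + r))
            noises.append(dfa_estimate(wn).alpha_hat)
            walks.append(dfa_estimate(integrate_series(wn)).alpha_hat)
        assert np.mean(walks) == pytest.approx(1.5, abs=0.1)
        assert np.std(walks, ddof=1) > np.std(noises, ddof=1)

    def test_sklearn_interface(self):
        est = DFA(n_max=256)
        assert est.get_params()["n_max"] == 256
        est.fit(davies_harte_fgn(0.5, 1024, RandomStreams(1)))
        assert hasattr(est, "alpha_") and est.bin_sizes_.size == 18
        assert est.result_.method == "DFA"
        assert 0 < est.r_squared_ <= 1

    def test_original_unbinned_variant(self):
        s = davies_harte_fgn(0.5, 1024, RandomStreams(2))
        est = DFA(evenly_spaced=False).fit(s)
        assert est.bin_sizes_.size == 503  # every n in [10, 512]
        assert abs(est.alpha_ - 0.5) < 0.25


class TestPsdPreprocess:
    def test_constant_becomes_zero(self):
        out = psd_preprocess(Series(np.full(64, 7.0)))
        assert np.allclose(out.values, 0.0)

    def test_window_shape(self):
        N = 1024
        t = np.arange(1, N + 1)
        w = 1 - (2 * t / (N + 1) - 1) ** 2
        assert w[0] == pytest.approx(1 - (2 / 1025 - 1) ** 2)  # ~0.003902
        assert np.allclose(w, w[::-1])  # symmetric
        assert w.max() == pytest.approx(w[(N - 1) // 2], abs=1e-6)

    def test_bridge_detrend_zeroes_endpoints(self):
        x = np.random.default_rng(3).standard_normal(128)
        out = psd_preprocess(Series(x))
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[-1] == pytest.approx(0.0, abs=1e-12)


class TestPeriodogram:
    def test_pure_cosine_peak(self):
        N, k = 256, 10
        t = np.arange(N)
        pg = periodogram(np.cos(2 * np.pi * k * t / N))
        peak = np.argmax(pg.powers)
        assert pg.frequencies[peak] == pytest.approx(k / N)
        others = np.delete(pg.powers, peak)
        assert pg.powers[peak] >= 1e3 * others.max()

    def test_matches_naive_dft(self):
        x = np.random.default_rng(8).standard_normal(64)
        pg = periodogram(x)
        t = np.arange(64)
        naive = np.array([
            abs(np.sum(x * np.exp(-2j * np.pi * j * t / 64))) ** 2
            for j in range(1, 32)
        ])
        assert np.max(np.abs(pg.powers - naive) / naive) < 1e-8

    def test_parseval_consistency(self):
        # for a mean-removed even-length series:
        # N sum x^2 = 2 sum_j I_j + |X(Nyquist)|^2
        x = np.random.default_rng(9).standard_normal(128)
        x -= x.mean()
        pg = periodogram(x)
        nyq = abs(np.fft.rfft(x)[-1]) ** 2
        assert 128 * float(x @ x) == pytest.approx(2 * pg.powers.sum() + nyq)


class TestPsdEstimator:
    def test_white_noise_flat_spectrum(self):
        betas = [
            psd_estimate(davies_harte_fgn(0.5, 1024, RandomStreams(900 + r))).native_estimate
            for r in range(120)
        ]
        assert abs(np.mean(betas)) < 0.05

    def test_recovers_ssm_target_slope(self):
        from fractalbench.generators import ssm_series
        betas = [
            psd_estimate(ssm_series(1.5, 1024, RandomStreams(950 + r))).native_estimate
            for r in range(120)
        ]
        assert np.mean(betas) == pytest.approx(1.5, abs=0.1)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            psd_estimate(np.random.default_rng(0).standard_normal(64))

    def test_retains_lowest_eighth_of_frequencies(self):
        est = LowPSD().fit(davies_harte_fgn(0.5, 1024, RandomStreams(1)))
        assert est.frequencies_.size == 64  # N=1024: f_j <= 1/16 -> j <= 64
        assert est.alpha_ == pytest.approx((est.beta_ + 1) / 2)


class TestWhittle:
    def _pg(self, seed=4, N=1024):
        x = davies_harte_fgn(0.7, N, RandomStreams(seed)).values
        return periodogram(x - x.mean())

    def test_d_zero_reduces_to_log_mean_power(self):
        pg = self._pg()
        assert whittle_objective(0.0, pg) == pytest.approx(
            math.log(np.mean(pg.powers)))

    def test_scale_invariance_of_minimiser(self):
        pg = self._pg()
        scaled = type(pg)(pg.frequencies, 2.0 * pg.powers)
        d = np.linspace(-0.45, 0.45, 91)
        base = np.array([whittle_objective(di, pg) for di in d])
        shifted = np.array([whittle_objective(di, scaled) for di in d])
        assert np.allclose(shifted - base, math.log(2.0), atol=1e-12)

    def test_optimizer_matches_grid_search(self):
        pg = self._pg(seed=12)
        grid = np.arange(-0.4999, 0.4999, 1e-4)
        d_grid = grid[np.argmin([whittle_objective(d, pg) for d in grid])]
        x = davies_harte_fgn(0.7, 1024, RandomStreams(12)).values
        d_opt = WhittleARFIMA().fit(x).d_
        assert abs(d_opt - d_grid) < 1e-3

    def test_d_range_validated(self):
        with pytest.raises(ValueError):
            whittle_objective(0.6, self._pg())


class TestWhittleEstimator:
    def test_white_noise(self):
        ds = [
            arfima_estimate(davies_harte_fgn(0.5, 1024, RandomStreams(r))).native_estimate
            for r in range(120)
        ]
        assert abs(np.mean(ds)) < 0.01

    def test_integrated_white_noise_classified_fbm(self):
        alphas = []
        for r in range(120):
            s = integrate_series(davies_harte_fgn(0.5, 1024, RandomStreams(r)))
            res = arfima_estimate(s)
            assert res.diagnostics["signal_class"] == SignalClass.FBM.value
            alphas.append(res.alpha_hat)
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.02)

    def test_parameter_recovery(self):
        ds = [
            arfima_estimate(arfima_fgn(0.4, 1024, RandomStreams(r))).native_estimate
            for r in range(120)
        ]
        assert np.mean(ds) == pytest.approx(0.4, abs=0.01)

    def test_boundary_diagnostics_exposed(self):
        s = integrate_series(davies_harte_fgn(0.9, 1024, RandomStreams(17)))
        est = WhittleARFIMA().fit(s)
        assert est.d_original_ >= est.bound - 1e-6
        assert est.signal_class_ is SignalClass.FBM
        assert est.d_ == pytest.approx(est.d_diff_ + 1.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            arfima_estimate(np.zeros(64) + np.arange(64.0))


class TestAffineInvariance:
    @pytest.mark.parametrize("estimate", [dfa_estimate, psd_estimate, arfima_estimate])
    def test_shift_and_scale_leave_alpha_unchanged(self, estimate):
        x = davies_harte_fgn(0.7, 1024, RandomStreams(77)).values
        base = estimate(x).alpha_hat
        shifted = estimate(x + 42.0).alpha_hat
        scaled = estimate(3.5 * x).alpha_hat
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base, abs=1e-6)
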