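"""Point-process simulators: parameter recovery, spectra, reproducibility."""
import numpy as np
import pytest
from scipy import signal, stats

import ppmir
from ppmir import (
    HDIGParams,
    PATParams,
    PoleSpec,
    ar_coeffs_from_poles,
    calibrate_innovation_sd,
    simulate_common_driver,
    simulate_hdig,
    simulate_pat_process,
    simulate_renewal,
)
from ppmir.simulate import CARDIAC_POLES, LF_POLES, _invgauss


def interval_psd(series):
    """Periodogram of the inter-event intervals on a per-beat axis scaled to
    Hz via the mean interval (valid for near-1-s heartbeat intervals)."""
    w = np.diff(series.times)
    fs = 1.0 / w.mean()
    f, p = signal.welch(w - w.mean(), fs=fs, nperseg=min(1024, w.size // 4 * 2))
    return f, p


class TestPoles:
    def test_single_real_pole(self):
        np.testing.assert_allclose(ar_coeffs_from_poles([0.6]), [0.6])

    def test_lf_complex_pair(self):
        a = ar_coeffs_from_poles(LF_POLES)
        assert a[0] == pytest.approx(2 * 0.8 * np.cos(2 * np.pi * 0.1), abs=1e-12)
        assert a[1] == pytest.approx(-0.64, abs=1e-12)

    def test_cardiac_five_pole_round_trip(self):
        coeffs = ar_coeffs_from_poles(CARDIAC_POLES)
        assert coeffs.size == 5
        roots = np.roots(np.concatenate([[1.0], -coeffs]))
        np.testing.assert_allclose(
            np.sort(np.abs(roots)), [0.6, 0.8, 0.8, 0.92, 0.92], atol=1e-10
        )

    def test_unstable_pole_rejected(self):
        with pytest.raises(ValueError):
            ar_coeffs_from_poles([1.0])
        with pytest.raises(ValueError):
            ar_coeffs_from_poles([(1.01, 0.3)])

    def test_pole_spec_expands_conjugates(self):
        roots = PoleSpec(((0.5, 1.0),)).roots()
        assert roots.size == 2
        assert roots[0] == np.conj(roots[1])


class TestInverseGaussianSampler:
    def test_against_scipy_distribution(self):
        """Transformation sampler matches scipy.stats.invgauss (oracle)."""
        rng = np.random.default_rng(0)
        mu, lam = 1.0, 600.0
        draws = np.asarray(_invgauss(rng, np.full(20_000, mu), lam))
        ks = stats.kstest(draws, stats.invgauss(mu / lam, scale=lam).cdf)
        assert ks.pvalue > 0.01

    def test_moments(self):
        rng = np.random.default_rng(1)
        draws = np.asarray(_invgauss(rng, np.full(50_000, 1.0), 600.0))
        assert draws.mean() == pytest.approx(1.0, abs=0.002)
        assert draws.std() == pytest.approx(np.sqrt(1.0 / 600.0), rel=0.05)


class TestRenewal:
    def test_exponential_mean(self):
        s = simulate_renewal("exponential", 10_000, seed=3, rate=5.0)
        w = np.diff(s.times)
        sem = w.std() / np.sqrt(w.size)
        assert abs(w.mean() - 0.2) < 2 * sem + 1e-9

    def test_inverse_gaussian_sd(self):
        s = simulate_renewal("inverse_gaussian", 10_000, seed=4, mu=1.0, lam=600.0)
        w = np.diff(s.times)
        assert w.std() == pytest.approx(np.sqrt(1.0 / 600.0), rel=0.05)

    def test_gaussian_truncation_keeps_positive(self):
        s = simulate_renewal("gaussian", 2000, seed=5, mu=0.8, sigma=1.0)
        assert np.all(np.diff(s.times) > 0)

    @pytest.mark.parametrize("dist", ["exponential", "gaussian", "inverse_gaussian"])
    def test_event_count_and_monotonicity(self, dist):
        s = simulate_renewal(dist, 500, seed=6)
        assert s.n == 500
        assert np.all(np.diff(s.times) > 0)
        assert s.times[0] == 0.0

    def test_reproducible(self):
        a = simulate_renewal("exponential", 100, seed=7)
        b = simulate_renewal("exponential", 100, seed=7)
        np.testing.assert_array_equal(a.times, b.times)

    def test_poisson_fano_factor(self):
        s = simulate_renewal("exponential", 20_000, seed=8, rate=1.0)
        edges = np.arange(0.0, s.times[-1], 10.0)
        counts, _ = np.histogram(s.times, edges)
        fano = counts.var() / counts.mean()
        assert fano == pytest.approx(1.0, abs=0.15)


class TestHDIG:
    def test_zero_theta_reduces_to_renewal(self):
        p = HDIGParams(theta0=1.0, theta=np.zeros(3), lambda_shape=600.0)
        s = simulate_hdig(p, 5000, seed=9)
        assert np.diff(s.times).mean() == pytest.approx(1.0, abs=0.01)

    def test_intervals_strictly_positive(self):
        s = simulate_hdig(n_events=2000, seed=10)
        assert np.all(np.diff(s.times) > 0)

    def test_spectral_peaks_in_lf_and_hf_bands(self):
        s = simulate_hdig(n_events=10_000, seed=11)
        f, p = interval_psd(s)
        lf = (f >= 0.08) & (f <= 0.12)
        hf = (f >= 0.2) & (f <= 0.3)
        mid = (f > 0.13) & (f < 0.19)
        assert p[lf].max() > p[mid].max()
        assert p[hf].max() > p[mid].max()

    def test_reproducible(self):
        a = simulate_hdig(n_events=200, seed=12)
        b = simulate_hdig(n_events=200, seed=12)
        np.testing.assert_array_equal(a.times, b.times)

    def test_unstable_theta_rejected(self):
        with pytest.raises(ValueError):
            HDIGParams(theta=np.array([1.2]))


class TestPATProcess:
    def test_innovation_sd_white_noise(self):
        assert calibrate_innovation_sd(0.0, 0.0, 0.05) == pytest.approx(0.05)

    def test_innovation_sd_closed_form(self):
        a1, a2 = ar_coeffs_from_poles(LF_POLES)
        assert calibrate_innovation_sd(a1, a2, 0.085) == pytest.approx(0.0401, abs=0.0005)

    def test_innovation_sd_monte_carlo(self):
        a1, a2 = ar_coeffs_from_poles(LF_POLES)
        sd_u = calibrate_innovation_sd(a1, a2, 0.1)
        rng = np.random.default_rng(13)
        e = rng.normal(0, sd_u, 100_000)
        tau = signal.lfilter([1.0], [1.0, -a1, -a2], e)[1000:]
        assert tau.std() == pytest.approx(0.1, rel=0.02)

    def test_unstable_rejected(self):
        with pytest.raises(ValueError):
            calibrate_innovation_sd(1.5, 0.6, 0.1)

    def test_mean_and_sd_of_delays(self):
        x = simulate_hdig(n_events=10_000, seed=14)
        y = simulate_pat_process(x, PATParams(sigma_pat=0.085), seed=15)
        tau = y.times - x.times
        assert tau.mean() == pytest.approx(0.3, abs=0.01)
        assert tau.std() == pytest.approx(0.085, rel=0.05)

    def test_delay_spectrum_peaks_near_lf(self):
        x = simulate_hdig(n_events=10_000, seed=16)
        y = simulate_pat_process(x, PATParams(sigma_pat=0.085), seed=17)
        tau = y.times - x.times
        fs = 1.0 / np.diff(x.times).mean()
        f, p = signal.welch(tau - tau.mean(), fs=fs, nperseg=1024)
        assert 0.08 <= f[np.argmax(p)] <= 0.12

    def test_interleaving_at_small_delays(self):
        x = simulate_hdig(n_events=1000, seed=18)
        y = simulate_pat_process(x, PATParams(sigma_pat=0.010), seed=19)
        # exactly one pulse arrival between consecutive heartbeats
        counts = np.histogram(y.times, x.times)[0]
        assert np.all(counts == 1)

    def test_clip_flag(self):
        x = simulate_hdig(n_events=300, seed=20)
        y = simulate_pat_process(
            x, PATParams(sigma_pat=0.235), seed=21, on_violation="clip"
        )
        assert np.all(np.diff(y.times) > 0)


class TestCommonDriver:
    def test_y_after_x_mostly_and_increasing(self):
        x, y = simulate_common_driver(0.035, 500, seed=22)
        assert np.all(np.diff(x.times) > 0)
        assert np.all(np.diff(y.times) > 0)
        assert np.mean(y.times > x.times) > 0.99

    def test_lf_power_increases_with_sigma(self):
        powers = []
        for sigma in (0.010, 0.110, 0.235):
            x, _ = simulate_common_driver(
                sigma, 5000, seed=23, on_violation="clip"
            )
            f, p = interval_psd(x)
            lf = (f >= 0.04) & (f <= 0.15)
            powers.append(np.trapezoid(p[lf], f[lf]))
        assert powers[0] < powers[1] < powers[2]

    def test_reproducible(self):
        a = simulate_common_driver(0.085, 200, seed=24)
        b = simulate_common_driver(0.085, 200, seed=24)
        np.testing.assert_array_equal(a[0].times, b[0].times)
        np.testing.assert_array_equal(a[1].times, b[1].times)
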