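"""Window transfer functions, their derivatives, and the weight->kernel map."""

import numpy as np
import pytest

from stationary_dfa.windows import (
    GAUSSIAN_SIGMA_RATIO,
    KIYONO_NORMALIZATION,
    BoxcarWindow,
    CustomWindow,
    GaussianWindow,
    KiyonoWindow,
    boxcar_transfer,
    boxcar_transfer_dscale,
    gaussian_transfer,
    kiyono_weight,
    make_window,
    transfer_to_time_kernel,
)


class TestBoxcarTransfer:
    def test_dc_limit_is_one(self):
        for L in (1.0, 7.0, 101.5):
            assert boxcar_transfer(0, L, 1000) == 1.0

    def test_single_point_window_is_identity(self):
        # L = 1: the moving average is the point itself, detrending removes everything
        for f in (0, 1, 17, 500):
            assert boxcar_transfer(f, 1.0, 1000) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("f,L,T", [(3, 101, 30000), (1, 11, 64), (250, 333, 1000)])
    def test_matches_explicit_cosine_sum(self, f, L, T):
        # direct evaluation of (1/L) sum_{t=-M}^{M} cos(2 pi f t / T)
        M = (L - 1) // 2
        brute = np.sum(np.cos(2 * np.pi * f * np.arange(-M, M + 1) / T)) / L
        assert boxcar_transfer(f, L, T) == pytest.approx(brute, abs=1e-12)

    def test_random_triples_match_sum_oracle(self, rng):
        for _ in range(25):
            T = int(rng.integers(16, 5000))
            L = int(rng.integers(1, T // 2)) * 2 + 1
            f = int(rng.integers(0, T // 2 + 1))
            M = (L - 1) // 2
            brute = np.sum(np.cos(2 * np.pi * f * np.arange(-M, M + 1) / T)) / L
            assert boxcar_transfer(f, L, T) == pytest.approx(brute, abs=1e-10)

    def test_derivative_matches_finite_difference(self, rng):
        T = 4096
        for _ in range(20):
            f = int(rng.integers(1, T // 2))
            L = float(rng.uniform(2, 500))
            d = 1e-6 * L
            fd = (boxcar_transfer(f, L + d, T) - boxcar_transfer(f, L - d, T)) / (2 * d)
            assert boxcar_transfer_dscale(f, L, T) == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            boxcar_transfer(1, -1.0, 100)
        with pytest.raises(ValueError):
            boxcar_transfer(51, 5, 100)  # above Nyquist index
        with pytest.raises(ValueError):
            boxcar_transfer(-1, 5, 100)


class TestGaussianTransfer:
    def test_dc_limit_and_zero_weight(self):
        assert gaussian_transfer(0, 5.0, 100) == 1.0
        w = GaussianWindow(5.0).weight(np.arange(51), 100)
        assert w[0] == 0.0

    def test_vanishing_sigma_gives_unit_transfer(self):
        assert gaussian_transfer(10, 1e-12, 1000) == pytest.approx(1.0, abs=1e-12)

    def test_high_precision_value(self):
        # exp(-2 pi^2 (f/T)^2 sigma^2) at f=10, sigma=1000/sqrt(12), T=100000,
        # evaluated independently with 30-digit arithmetic
        sigma = 1000.0 * GAUSSIAN_SIGMA_RATIO
        assert gaussian_transfer(10, sigma, 100000) == pytest.approx(
            0.983685210963655946100130163478, abs=1e-15
        )

    def test_decays_faster_than_boxcar_envelope(self):
        # motivation for the Gaussian window: its weight reaches 1 smoothly
        # while the boxcar weight keeps oscillating within a 1/(L sin(pi f/T))
        # envelope at high frequency
        T, L = 10000, 101
        sigma = L * GAUSSIAN_SIGMA_RATIO
        f = np.arange(T // 8, T // 2 + 1)
        wg = GaussianWindow(sigma).weight(f, T)
        wb = BoxcarWindow(L).weight(f, T)
        envelope = (1.0 + 1.0 / (L * np.sin(np.pi * f / T))) ** 2
        assert np.all(wb <= envelope + 1e-12)
        assert np.all(np.abs(wg - 1.0) <= np.abs(envelope - 1.0) + 1e-12)


class TestKiyonoWeight:
    def test_zero_at_dc(self):
        for order in (0, 1):
            assert kiyono_weight(0, 100.0, 1000, order) == 0.0

    def test_order0_closed_form_at_half(self):
        # u = fL/T = 1/2: raw h0 = (2 pi^2 (1/4) + cos(pi) - 1)/(1/4) = 2 pi^2 - 8
        T, L = 1000, 100
        f = T / (2 * L) * np.array([1.0])  # u = 1/2 requires f = T/(2L)
        raw = kiyono_weight(f, L, T, 0, raw=True)
        assert raw[0] == pytest.approx(2 * np.pi**2 - 8, abs=1e-12)
        norm = kiyono_weight(f, L, T, 0)
        assert norm[0] == pytest.approx((2 * np.pi**2 - 8) / KIYONO_NORMALIZATION[0], abs=1e-12)

    @pytest.mark.parametrize("order", [0, 1])
    def test_matches_phase_average_oracle(self, order):
        """The weight equals twice the phase-averaged variance of an
        order-n detrended unit oscillation over one segment."""

        def oracle(u, n_t=2001, n_phase=48):
            t = np.linspace(0.0, 1.0, n_t)
            cols = [np.ones(n_t)] + ([t] if order == 1 else [])
            A = np.column_stack(cols)
            P = A @ np.linalg.pinv(A)
            vals = []
            for ph in np.linspace(0, 2 * np.pi, n_phase, endpoint=False):
                y = np.cos(2 * np.pi * u * t + ph)
                z = y - P @ y
                vals.append(np.trapezoid(z**2, t))
            return 2.0 * np.mean(vals)

        T, L = 10000, 1000
        for u in np.linspace(0.15, 5.0, 15):
            f = np.array([u * T / L])
            got = kiyono_weight(f, L, T, order)[0]
            assert got == pytest.approx(oracle(u), rel=1e-2)

    @pytest.mark.parametrize("order", [0, 1])
    def test_nonnegative_and_finite_near_zero(self, order):
        T = 100000
        f = np.arange(0, 200)
        w = kiyono_weight(f, 3.0, T, order)
        assert np.all(np.isfinite(w))
        assert np.all(w >= 0.0)

    @pytest.mark.parametrize("order", [0, 1])
    def test_series_direct_crossover_is_smooth(self, order):
        # values on both sides of the small-argument switch agree smoothly
        T, L = 1000000, 1000
        us = np.linspace(0.005, 0.1, 400)
        w = kiyono_weight(us * T / L, L, T, order)
        ratio = np.diff(np.log(w))
        assert np.all(np.abs(np.diff(ratio)) < 0.05)

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            kiyono_weight(1, 10.0, 100, 2)


class TestTimeKernel:
    def test_boxcar_roundtrip(self):
        T, L = 4096, 101
        w = BoxcarWindow(L).weight(np.arange(T // 2 + 1), T)
        kernel = transfer_to_time_kernel(w, L, T)
        M = (L - 1) // 2
        expected = np.zeros(T)
        expected[: M + 1] = 1.0 / L
        expected[-M:] = 1.0 / L
        assert np.abs(kernel - expected).max() < 1e-10

    def test_kernel_is_real_and_symmetric(self):
        T, L = 2048, 333
        kernel = transfer_to_time_kernel(
            lambda f, scale, T_: np.asarray(KiyonoWindow(scale, 0).weight(f, T_)), L, T
        )
        assert kernel.dtype.kind == "f"
        assert np.allclose(kernel[1:], kernel[1:][::-1], atol=1e-12)

    def test_kiyono0_kernel_shape(self):
        # decreases steadily up to twice the segment length, then much slower
        T, L = 32768, 1000
        f = np.arange(T // 2 + 1)
        k = transfer_to_time_kernel(kiyono_weight(f, L, T, 0), L, T)[: T // 2]
        assert k[0] > 0
        assert np.all(np.diff(k[: 2 * L]) < 1e-9)  # monotone decrease to 2L
        early_rate = (k[0] - k[2 * L]) / (2 * L)
        late_rate = (k[2 * L] - k[4 * L]) / (2 * L)
        assert late_rate < 0.05 * early_rate

    def test_kiyono1_kernel_resembles_gaussian_but_dips_negative(self):
        T, L = 32768, 1000
        f = np.arange(T // 2 + 1)
        k1 = transfer_to_time_kernel(kiyono_weight(f, L, T, 1), L, T)[: T // 2]
        gauss = transfer_to_time_kernel(
            np.asarray(GaussianWindow(L * GAUSSIAN_SIGMA_RATIO).weight(f, T)), L, T
        )[: T // 2]
        assert k1.min() < 0.0
        assert k1[0] == pytest.approx(gauss[0], rel=0.25)

    def test_rejects_negative_weight(self):
        T = 256
        w = -0.1 * np.ones(T // 2 + 1)
        with pytest.raises(ValueError):
            transfer_to_time_kernel(w, 10.0, T)


class TestWindowObjects:
    @pytest.mark.parametrize("family", ["boxcar", "gaussian", "kiyono0", "kiyono1"])
    def test_weight_zero_at_dc_and_nonnegative(self, family):
        win = make_window(family, 50.0, scale_is_boxcar_width=True)
        w = np.asarray(win.weight(np.arange(0, 513), 1024))
        assert w[0] == 0.0
        assert np.all(w >= 0.0)

    def test_nyquist_guard(self):
        win = make_window("boxcar", 11.0)
        with pytest.raises(ValueError):
            win.weight(np.array([600]), 1024)

    def test_custom_window_requires_zero_dc(self):
        bad = CustomWindow(5.0, weight_fn=lambda f, s, T: np.ones_like(np.asarray(f, float)))
        with pytest.raises(ValueError):
            bad.weight(np.arange(10), 100)

    def test_custom_window_finite_difference_derivative(self):
        # custom weight mimicking the gaussian family must reproduce its derivative
        def wfn(f, s, T):
            u = np.asarray(f, float) / T
            return (-np.expm1(-2 * np.pi**2 * u**2 * s**2)) ** 2

        cw = CustomWindow(30.0, weight_fn=wfn)
        gw = GaussianWindow(30.0)
        f = np.arange(1, 100)
        a = np.asarray(cw.dweight_dscale(f, 1024))
        b = np.asarray(gw.dweight_dscale(f, 1024))
        # compare where the derivative is numerically significant; below
        # ~1e-9 of the peak the finite-difference fallback drowns in rounding
        sel = np.abs(b) > 1e-9 * np.abs(b).max()
        assert np.allclose(a[sel], b[sel], rtol=1e-4)

    def test_gaussian_equivalent_scale(self):
        win = make_window("gaussian", 1000.0, scale_is_boxcar_width=True)
        assert win.scale == pytest.approx(1000.0 / np.sqrt(12.0))
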