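import numpy as np
import pytest

from ppgpulse.volterra_anc import (
    VolterraConfig,
    build_design,
    expansion_dim,
    rls_denoise,
    shift_reference,
    volterra_expand,
)


def weighted_ls_weights(x, a, memory, lam, order=2):
    """Independent closed-form oracle: exponentially weighted least squares
    over samples 0..k solved directly via the normal equations."""
    phi = build_design(a, memory, order)
    k = x.size - 1
    wts = lam ** (k - np.arange(x.size))
    A = (phi * wts[:, None]).T @ phi
    b = (phi * wts[:, None]).T @ x
    return np.linalg.solve(A, b)


class TestExpansion:
    def test_dimension_counts_linear_plus_products(self):
        assert expansion_dim(2) == 9  # 3 linear + 6 products
        assert expansion_dim(0) == 2
        assert expansion_dim(10) == 77

    def test_memory_zero_gives_value_and_square(self):
        vec = volterra_expand(np.array([2.0]), 0, 0)
        np.testing.assert_allclose(vec, [2.0, 4.0])

    def test_zero_reference_gives_zero_vector(self):
        vec = volterra_expand(np.zeros(10), 5, 3)
        assert np.all(vec == 0)

    def test_design_rows_match_per_sample_expansion(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        phi = build_design(a, 3)
        for i in (0, 3, 10, 19):
            np.testing.assert_allclose(phi[i], volterra_expand(a, i, 3))


class TestShiftReference:
    def test_positive_shift_delays_and_zero_pads(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(shift_reference(a, 2), [0, 0, 1, 2])

    def test_zero_shift_is_identity(self):
        a = np.array([1.0, 2.0])
        np.testing.assert_allclose(shift_reference(a, 0), a)


class TestRLS:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("memory", [0, 1, 2])
    def test_recursion_matches_closed_form(self, seed, memory):
        """Exponentially weighted RLS equals the direct normal-equation
        solution up to the inverse-correlation initialisation."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=50)
        x = rng.normal(size=50)
        cfg = VolterraConfig(memory=memory, lam=1.0, init_diag=1e7, delay_s=0.0)
        _, state = rls_denoise(x, a, cfg)
        w_direct = weighted_ls_weights(x, a, memory, 1.0)
        np.testing.assert_allclose(state.w, w_direct, atol=1e-6)

    def test_forgetting_factor_matches_weighted_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=80)
        x = rng.normal(size=80)
        cfg = VolterraConfig(memory=1, lam=0.98, init_diag=1e7, delay_s=0.0)
        _, state = rls_denoise(x, a, cfg)
        w_direct = weighted_ls_weights(x, a, 1, 0.98)
        np.testing.assert_allclose(state.w, w_direct, atol=1e-5)

    def test_pure_linear_noise_is_cancelled(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=2000)
        x = 0.5 * a
        cfg = VolterraConfig(memory=0, lam=0.999, delay_s=0.0)
        s_hat, state = rls_denoise(x, a, cfg)
        tail = s_hat[1000:]
        assert np.sqrt(np.mean(tail**2)) < 0.05 * np.sqrt(np.mean(x**2))
        assert state.w[0] == pytest.approx(0.5, abs=0.05)

    def test_pulse_survives_linear_artifact(self):
        fs = 125.0
        t = np.arange(1000) / fs
        rng = np.random.default_rng(2)
        a = np.sin(2 * np.pi * 2.3 * t) + 0.05 * rng.normal(size=1000)
        pulse = np.sin(2 * np.pi * 1.7 * t)
        x = pulse + 2.0 * a
        cfg = VolterraConfig(memory=10, lam=0.999, delay_s=0.0)
        s_hat, _ = rls_denoise(x, a, cfg, burn_in=True)
        amp = np.abs(np.fft.rfft(s_hat, 4096))
        amp_clean = np.abs(np.fft.rfft(pulse, 4096))
        b17 = int(round(1.7 * 4096 / fs))
        assert amp[b17] >= 0.5 * amp_clean[b17]

    def test_zero_reference_leaves_signal_untouched(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        s_hat, _ = rls_denoise(x, np.zeros(500), VolterraConfig(delay_s=0.0))
        np.testing.assert_array_equal(s_hat, x)

    def test_output_length_matches_input(self):
        rng = np.random.default_rng(4)
        x, a = rng.normal(size=(2, 300))
        s_hat, _ = rls_denoise(x, a, VolterraConfig(memory=5, delay_s=0.0))
        assert s_hat.shape == x.shape

    def test_non_finite_input_rejected(self):
        x = np.zeros(10)
        x[3] = np.nan
        with pytest.raises(ValueError):
            rls_denoise(x, np.zeros(10), VolterraConfig(delay_s=0.0))

    def test_quadratic_artifact_needs_second_order(self):
        """A linear-only canceller cannot remove the squared-reference
        component (it lives at twice the reference frequency)."""
        fs = 125.0
        t = np.arange(1000) / fs
        rng = np.random.default_rng(5)
        a = np.sin(2 * np.pi * 2.0 * t) + 0.05 * rng.normal(size=1000)
        x = 1.0 * a + 1.0 * a**2
        b4 = int(round(4.0 * 4096 / fs))
        residuals = {}
        for order in (1, 2):
            cfg = VolterraConfig(memory=10, lam=0.999, delay_s=0.0, order=order)
            s_hat, _ = rls_denoise(x, a, cfg, burn_in=True)
            amp = np.abs(np.fft.rfft(s_hat, 4096))
            residuals[order] = np.sum(amp[b4 - 2 : b4 + 3] ** 2)
        assert residuals[1] > 2 * residuals[2]
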