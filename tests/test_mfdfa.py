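import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respiro import (
    MFDFAParams,
    ParameterError,
    fluctuation_function,
    gen_binomial_cascade,
    gen_fgn,
    hurst_exponents,
    mass_exponent,
    mfdfa,
    multifractal_spectrum,
    profile,
    cascade_hq,
)
from respiro.mfdfa import DegenerateDetrendError, default_scales
from conftest import brute_force_fluctuation

Q5 = np.arange(-5.0, 6.0)


class TestProfile:
    def test_zero_mean_cumsum(self):
        np.testing.assert_allclose(profile([1, -1, 1, -1]), [1, 0, 1, 0])

    def test_constant_series_all_zeros(self):
        np.testing.assert_allclose(profile(np.full(10, 3.0)), 0.0, atol=1e-12)

    def test_last_value_telescopes_to_zero(self):
        x = np.random.default_rng(0).standard_normal(500) * 10
        assert abs(profile(x)[-1]) < 1e-9 * x.size * x.std()


class TestFluctuationFunction:
    def test_q2_reduces_to_dfa(self):
        Y = profile(np.random.default_rng(1).standard_normal(64))
        f = fluctuation_function(Y, 8, [2.0], 1)
        # ordinary DFA: RMS over segment mean squared residuals
        oracle = brute_force_fluctuation(Y, 8, [2.0], 1)
        np.testing.assert_allclose(f, oracle, atol=1e-12)

    def test_degenerate_on_polynomial_profile(self):
        # a linear series has a quadratic profile: order-2 detrending
        # leaves zero residual everywhere
        Y = profile(np.linspace(0, 1, 32))
        with pytest.raises(DegenerateDetrendError):
            fluctuation_function(Y, 8, [2.0], 2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([8, 11, 16]),
           st.integers(1, 2))
    def test_matches_loop_level_oracle(self, seed, s, poly_order):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2 * s, 65))
        Y = profile(rng.standard_normal(n))
        q = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 4.0])
        got = fluctuation_function(Y, s, q, poly_order)
        want = brute_force_fluctuation(Y, s, q, poly_order)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-13)


class TestExponents:
    def test_mass_exponent_identities(self):
        q = np.arange(-3.0, 4.0)
        tau = mass_exponent(np.full(q.size, 0.7), q)
        np.testing.assert_allclose(tau, q * 0.7 - 1)
        assert tau[q == 0] == -1.0

    def test_monofractal_spectrum_is_a_point(self):
        q = np.arange(-5.0, 6.0)
        tau = q * 0.8 - 1
        alpha, f = multifractal_spectrum(tau, q)
        np.testing.assert_allclose(alpha, 0.8, atol=1e-12)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_spectrum_rejects_unsorted_q(self):
        with pytest.raises(ParameterError):
            multifractal_spectrum([0.0, 1.0, 2.0], [1.0, 0.0, 2.0])

    def test_cascade_tau_concave(self):
        c = gen_binomial_cascade(14, 0.6)
        res = mfdfa(c, MFDFAParams(scales=2 ** np.arange(4, 11), q_list=Q5))
        assert np.all(np.diff(res.tauq, 2) <= 1e-8)

    def test_too_few_scales_in_fit_range(self):
        Fq = np.ones((3, 5))
        with pytest.raises(Exception, match="scales"):
            hurst_exponents(Fq, [8, 16, 32, 64, 128], [0, 1, 2], fit_range=(60, 70))


class TestMFDFAEndToEnd:
    def test_white_noise_h2_near_half_and_flat_hq(self):
        h2s, widths = [], []
        for seed in range(5):
            x = gen_fgn(2 ** 13, 0.5, seed)
            res = mfdfa(x, MFDFAParams(scales=default_scales(x.size), q_list=Q5))
            h2s.append(res.hq[Q5 == 2.0][0])
            widths.append(res.hq[0] - res.hq[-1])
        assert abs(np.mean(h2s) - 0.5) < 0.05
        assert -0.1 <= np.mean(widths) <= 0.15

    def test_cascade_hq_decreasing_and_matches_closed_form(self):
        c = gen_binomial_cascade(14, 0.7)
        res = mfdfa(c, MFDFAParams(scales=2 ** np.arange(4, 11), q_list=Q5))
        assert np.all(np.diff(res.hq) < 1e-6)
        np.testing.assert_allclose(
            res.hq[Q5 != 0], cascade_hq(Q5[Q5 != 0], 0.7), atol=0.06)

    def test_hq_non_increasing_within_tolerance_on_noise(self):
        x = np.random.default_rng(9).standard_normal(4096)
        res = mfdfa(x, MFDFAParams(scales=default_scales(x.size), q_list=Q5))
        assert np.all(np.diff(res.hq) <= 0.02)

    def test_f2_grows_with_scale(self):
        # F_2(s) averaged over realizations increases with window size
        scales = 2 ** np.arange(3, 10)
        acc = np.zeros(scales.size)
        for seed in range(5):
            x = gen_fgn(2 ** 12, 0.5, seed + 100)
            res = mfdfa(x, MFDFAParams(scales=scales, q_list=np.array([2.0])))
            acc += np.log(res.Fq[0])
        assert np.all(np.diff(acc) > 0)

    def test_series_too_short(self):
        with pytest.raises(ParameterError):
            mfdfa(np.random.default_rng(3).standard_normal(10))
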