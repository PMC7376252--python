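"""Cosinor fitting, zero-amplitude testing and rhythm calls."""



import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import f_test_oracle, grid_search_cosinor
from rhythmkit import (
    EstimabilityError,
    call_rhythm,
    canonicalize,
    fit_cosinor,
    linearized_fit,
    predict,
    zero_amplitude_test,
)
from rhythmkit.cosinor import ND, NSR, RHYTHMIC

ZT = np.array([3.0, 9.0, 15.0, 21.0])


def cosine(t, m, a, phi, period=24.0):
    return m + a * np.cos(2 * np.pi * (t - phi) / period)


class TestExactRecovery:
    @pytest.mark.parametrize(
        "m,a,phi", [(5.0, 2.0, 8.0), (0.0, 1.0, 0.0), (-3.0, 0.5, 23.9), (10.0, 4.0, 12.0)]
    )
    def test_noise_free_interpolation(self, m, a, phi):
        t = np.tile(ZT, 3)
        fit = fit_cosinor(t, cosine(t, m, a, phi))
        assert fit.params.mesor == pytest.approx(m, abs=1e-9)
        assert fit.params.amplitude == pytest.approx(a, abs=1e-9)
        assert fit.params.acrophase == pytest.approx(phi, abs=1e-9)
        assert fit.sse_full <= 1e-9
        assert fit.p_zero_amplitude == 0.0
        assert fit.call == RHYTHMIC

    def test_constant_series_has_undefined_phase(self):
        fit = fit_cosinor(np.tile(ZT, 3), np.full(12, 4.2))
        assert fit.params.mesor == pytest.approx(4.2)
        assert fit.params.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.params.acrophase == 0.0
        assert not fit.params.phase_defined
        assert fit.p_zero_amplitude == 1.0
        assert fit.call == NSR


class TestOracles:
    def test_grid_search_oracle_on_noisy_fixture(self, noisy_16pt):
        t, y = noisy_16pt
        fit = fit_cosinor(t, y)
        m, a, phi = grid_search_cosinor(t, y)
        assert fit.params.mesor == pytest.approx(m, abs=1e-3)
        assert fit.params.amplitude == pytest.approx(a, abs=1e-3)
        assert fit.params.acrophase == pytest.approx(phi, abs=1e-3)

    def test_f_statistic_matches_sse_arithmetic(self, noisy_16pt):
        t, y = noisy_16pt
        fit = fit_cosinor(t, y)
        f_ref, p_ref = f_test_oracle(
            t, y, fit.params.mesor, fit.params.amplitude, fit.params.acrophase
        )
        assert fit.f_statistic == pytest.approx(f_ref, abs=1e-9)
        assert fit.p_zero_amplitude == pytest.approx(p_ref, abs=1e-9)

    def test_nonlinear_equals_closed_form_on_random_inputs(self, rng):
        for _ in range(200):
            n_rep = rng.integers(3, 7)
            t = np.repeat(ZT, n_rep) + rng.normal(0, 0.1, 4 * n_rep)
            y = cosine(t, rng.normal(0, 5), rng.uniform(0.1, 5), rng.uniform(0, 24))
            y = y + rng.normal(0, rng.uniform(0.05, 2.0), t.size)
            full = fit_cosinor(t, y).params
            lin = linearized_fit(t, y)
            scale = max(abs(lin.mesor), lin.amplitude, 1.0)
            assert abs(full.mesor - lin.mesor) <= 1e-8 * scale
            assert abs(full.amplitude - lin.amplitude) <= 1e-8 * scale
            dphi = (full.acrophase - lin.acrophase + 12.0) % 24.0 - 12.0
            assert abs(dphi) <= 1e-6


class TestHarmonicConvention:
    def test_pure_cosine_peaks_at_zero(self):
        t = np.tile(ZT, 2)
        p = linearized_fit(t, np.cos(2 * np.pi * t / 24.0))
        assert p.amplitude == pytest.approx(1.0, abs=1e-12)
        assert min(p.acrophase, 24.0 - p.acrophase) == pytest.approx(0.0, abs=1e-9)

    def test_pure_sine_peak_matches_predict(self):
        # y = sin(omega t) peaks at t = 6 for a 24 h period; the fitted
        # acrophase must coincide with the argmax of predict()
        t = np.tile(ZT, 2)
        p = linearized_fit(t, np.sin(2 * np.pi * t / 24.0))
        assert p.amplitude == pytest.approx(1.0, abs=1e-12)
        assert p.acrophase == pytest.approx(6.0, abs=1e-9)
        grid = np.linspace(0, 24, 100_000, endpoint=False)
        assert grid[np.argmax(predict(p, grid))] == pytest.approx(p.acrophase, abs=1e-3)

    def test_two_distinct_timepoints_not_estimable(self):
        t = np.array([0.0, 0.0, 12.0, 12.0])
        with pytest.raises(EstimabilityError):
            linearized_fit(t, np.array([1.0, 2.0, 3.0, 4.0]))
        assert fit_cosinor(t, np.array([1.0, 2.0, 3.0, 4.0])).call == ND

    def test_aliased_timepoints_not_estimable(self):
        # 0, 24, 48 are one point modulo the period
        t = np.array([0.0, 24.0, 48.0, 8.0, 16.0])
        linearized_fit(t, np.arange(5.0))  # 3 distinct residues: fine
        t_bad = np.array([0.0, 24.0, 48.0, 72.0])
        with pytest.raises(EstimabilityError):
            linearized_fit(t_bad, np.arange(4.0))


class TestRhythmCall:
    @pytest.mark.parametrize(
        "p,expected", [(0.049, RHYTHMIC), (0.05, NSR), (0.51, NSR), (float("nan"), ND)]
    )
    def test_threshold_is_strict(self, p, expected):
        assert call_rhythm(p, alpha=0.05) == expected

    def test_mostly_missing_series_is_nd(self):
        t = np.tile(ZT, 3)
        y = cosine(t, 5, 2, 8)
        y[:7] = np.nan  # > 50% below detection floor
        assert fit_cosinor(t, y).call == ND

    def test_zero_amplitude_test_needs_df(self):
        with pytest.raises(ValueError):
            zero_amplitude_test(1.0, 2.0, n=3)


class TestPredict:
    def test_peak_trough_and_periodicity(self):
        p = canonicalize(5.0, 2.0, 8.0)
        assert predict(p, 8.0) == pytest.approx(7.0)
        assert predict(p, 20.0) == pytest.approx(3.0)
        assert predict(p, 8.0 + 24.0) == pytest.approx(predict(p, 8.0))

    def test_mean_over_period_is_mesor(self):
        p = canonicalize(3.7, 1.9, 13.0)
        grid = np.linspace(0, 24, 10_000, endpoint=False)
        assert np.mean(predict(p, grid)) == pytest.approx(p.mesor, abs=1e-6)


class TestEquivariance:
    @given(
        shift=st.floats(-48, 48),
        m=st.floats(-10, 10),
        a=st.floats(0.2, 5),
        phi=st.floats(0, 24, exclude_max=True),
        noise_seed=st.integers(0, 2**16),
    )
    def test_time_shift_moves_acrophase(self, shift, m, a, phi, noise_seed):
        r = np.random.default_rng(noise_seed)
        t = np.repeat(ZT, 3)
        y = cosine(t, m, a, phi) + r.normal(0, 0.5, t.size)
        base = linearized_fit(t, y)
        moved = linearized_fit(t + shift, y)
        assert moved.mesor == pytest.approx(base.mesor, abs=1e-8)
        assert moved.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        dphi = (moved.acrophase - base.acrophase - shift + 12.0) % 24.0 - 12.0
        assert abs(dphi) <= 1e-6

    @given(
        scale=st.floats(-4, 4).filter(lambda a: abs(a) > 0.01),
        offset=st.floats(-20, 20),
        noise_seed=st.integers(0, 2**16),
    )
    def test_value_affine_maps_mesor_amplitude(self, scale, offset, noise_seed):
        r = np.random.default_rng(noise_seed)
        t = np.repeat(ZT, 3)
        y = cosine(t, 5, 2, 8) + r.normal(0, 0.5, t.size)
        base = linearized_fit(t, y)
        mapped = linearized_fit(t, scale * y + offset)
        assert mapped.mesor == pytest.approx(scale * base.mesor + offset, abs=1e-7)
        assert mapped.amplitude == pytest.approx(abs(scale) * base.amplitude, abs=1e-7)
        expected_phi = base.acrophase if scale > 0 else (base.acrophase + 12.0) % 24.0
        dphi = (mapped.acrophase - expected_phi + 12.0) % 24.0 - 12.0
        assert abs(dphi) <= 1e-6

    @given(
        m=st.floats(-10, 10),
        a=st.floats(0.01, 10),
        phi=st.floats(-30, 60),
    )
    def test_canonicalization_preserves_predictions(self, m, a, phi):
        canon = canonicalize(m, -a, phi)
        assert canon.amplitude == pytest.approx(a)
        assert 0 <= canon.acrophase < 24
        grid = np.linspace(0, 24, 97)
        direct = m + (-a) * np.cos(2 * np.pi * (grid - phi) / 24.0)
        np.testing.assert_allclose(predict(canon, grid), direct, atol=1e-9)


def test_parameter_recovery_at_study_design(rng):
    """Median estimation error at the sparse around-the-clock design.

    4 time points x 5 replicates, amplitude twice the noise SD: the
    amplitude should typically be recovered within 25% and the acrophase
    within 1.5 h (circular).
    """
    t = np.repeat(ZT, 5)
    amp_err, phi_err = [], []
    for _ in range(500):
        phi = rng.uniform(0, 24)
        y = cosine(t, 5.0, 2.0, phi) + rng.normal(0, 1.0, t.size)
        p = linearized_fit(t, y)
        amp_err.append(abs(p.amplitude - 2.0) / 2.0)
        phi_err.append(abs((p.acrophase - phi + 12.0) % 24.0 - 12.0))
    assert np.median(amp_err) <= 0.25
    assert np.median(phi_err) <= 1.5
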