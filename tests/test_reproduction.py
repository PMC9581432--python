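"""Basic reproduction number: closed form, case reductions, NGM cross-check."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exerdyn import (
    ModelParameters,
    Persistence,
    classify_persistence,
    coefficients,
    r0_case2,
    r0_case3,
    r0_closed_form,
    r0_ngm,
)
from exerdyn.errors import (
    CaseMismatchError,
    DegenerateFormulaError,
    DfeNotEquilibriumError,
    NonInvertibleTransitionError,
)

from conftest import rate

bounded_rate = st.floats(min_value=0.005, max_value=0.3, allow_nan=False)


class TestCoefficients:
    def test_transmission_free_zeroes_B_and_C(self):
        # every addend of B and C carries an r or k factor
        params = ModelParameters(
            beta1=0.3, beta2=0.1, delta1=0.2, delta2=0.4, alpha1=0.5, alpha2=0.6,
            gamma1=0.7, gamma2=0.8,
        )
        c = coefficients(params, S0=80.0, N=100.0)
        assert c.B == 0.0
        assert c.C == 0.0
        assert c.A > 0

    def test_case3_zeroing_collapses_symbolically(self):
        # with r2 = k2 = beta2 = delta2 = 0 the printed expressions reduce to
        # A = N*a1*(N*d1 + S0*b1), B = S0*N*a1*(k1 + r1), C = 0
        params = ModelParameters(
            r1=0.07, k1=0.03, beta1=0.11, delta1=0.05, alpha1=0.09, alpha2=0.13
        )
        S0, N = 60.0, 100.0
        c = coefficients(params, S0, N)
        assert c.A == pytest.approx(N * 0.09 * (N * 0.05 + S0 * 0.11), rel=1e-14)
        assert c.B == pytest.approx(S0 * N * 0.09 * (0.03 + 0.07), rel=1e-14)
        assert c.C == 0.0

    def test_cross_term_determinant_in_C(self):
        params = ModelParameters(r1=1.0, k2=1.0, beta1=0.1, delta1=0.2,
                                 alpha1=0.3, alpha2=0.4)
        c = coefficients(params, S0=2.0, N=10.0)
        assert c.C == 4.0  # (1*1 - 0*0) * 2^2

    @given(st.floats(min_value=0.0, max_value=0.5),
           st.floats(min_value=0.0, max_value=0.5))
    def test_spontaneous_uptake_absent_from_coefficients(self, g1, g2):
        base = ModelParameters(r1=0.02, k1=0.01, beta1=0.03, delta1=0.02,
                               alpha1=0.01, alpha2=0.01)
        perturbed = base.replace(gamma1=g1, gamma2=g2)
        c0 = coefficients(base, 50.0, 100.0)
        c1 = coefficients(perturbed, 50.0, 100.0)
        assert (c0.A, c0.B, c0.C) == (c1.A, c1.B, c1.C)


class TestClosedForm:
    def test_no_social_transmission_means_r0_zero(self):
        params = ModelParameters(beta1=0.01, beta2=0.01, delta1=0.01,
                                 delta2=0.01, alpha1=0.01, alpha2=0.01)
        result = r0_closed_form(params, S0=100.0, N=100.0)
        assert result.value == 0.0
        assert result.classification is Persistence.EXTINCTION

    def test_persistence_scenario_value(self, fig3a_params):
        # Case 2 pattern: general formula collapses to (k1 + r1)/beta1
        result = r0_closed_form(fig3a_params, S0=1000.0, N=1000.0)
        assert result.value == pytest.approx(0.017 / 0.0022, rel=1e-12)
        assert result.classification is Persistence.PERSISTENCE

    def test_extinction_scenario_value(self, fig3b_params):
        result = r0_closed_form(fig3b_params, S0=1000.0, N=1000.0)
        assert result.value == pytest.approx(0.017 / 0.035, rel=1e-12)
        assert result.classification is Persistence.EXTINCTION

    def test_degenerate_leading_coefficient_raises(self):
        # no recidivism or exchange at all -> A = 0
        params = ModelParameters(r1=0.1, k1=0.1)
        with pytest.raises(DegenerateFormulaError):
            r0_closed_form(params, S0=100.0, N=100.0)


class TestCaseReductions:
    def test_case2_persistence(self):
        result = r0_case2(ModelParameters(k1=0.002, r1=0.015, beta1=0.0022,
                                          alpha1=0.005, alpha2=0.005))
        assert result.value > 1
        assert result.classification is Persistence.PERSISTENCE

    def test_case2_extinction(self):
        result = r0_case2(ModelParameters(k1=0.002, r1=0.015, beta1=0.035,
                                          alpha1=0.005, alpha2=0.005))
        assert result.value < 1
        assert result.classification is Persistence.EXTINCTION

    def test_case2_equal_rates_give_two(self):
        params = ModelParameters(k1=0.04, r1=0.04, beta1=0.04)
        assert r0_case2(params).value == 2.0

    def test_case2_rejects_nonzero_excluded_parameter(self):
        with pytest.raises(CaseMismatchError, match="delta1"):
            r0_case2(ModelParameters(k1=0.01, beta1=0.01, delta1=0.02))

    def test_case2_rejects_zero_beta1(self):
        with pytest.raises(ZeroDivisionError):
            r0_case2(ModelParameters(k1=0.01))

    def test_case3_reduces_to_case2_when_delta1_zero_and_all_sedentary(self):
        params = ModelParameters(k1=0.03, r1=0.02, beta1=0.04, alpha1=0.01,
                                 alpha2=0.02)
        assert r0_case3(params, S0=100.0, N=100.0).value == pytest.approx(
            r0_case2(params).value, rel=1e-14
        )

    def test_case3_threshold_at_equality(self):
        # numerator (k1+r1)p equals denominator beta1*p + delta1 exactly;
        # values chosen binary-exact: 0.5*0.5 = 0.375*0.5 + 0.0625 = 0.25
        params = ModelParameters(k1=0.25, r1=0.25, beta1=0.375, delta1=0.0625,
                                 alpha1=0.01)
        result = r0_case3(params, S0=50.0, N=100.0)
        assert result.value == 1.0
        assert result.classification is Persistence.THRESHOLD
        assert result.persistence_inequality is False

    @given(
        st.floats(min_value=0.0, max_value=0.3),
        st.floats(min_value=0.0, max_value=0.3),
        bounded_rate, bounded_rate, bounded_rate, bounded_rate,
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_case3_matches_general_formula(self, r1, k1, beta1, delta1,
                                           alpha1, alpha2, frac):
        # with the Case 3 zeroing, C = 0 and the larger root is B/A
        params = ModelParameters(r1=r1, k1=k1, beta1=beta1, delta1=delta1,
                                 alpha1=alpha1, alpha2=alpha2)
        N = 1000.0
        special = r0_case3(params, frac * N, N)
        general = r0_closed_form(params, frac * N, N)
        assert special.value == pytest.approx(general.value, rel=1e-10)
        assert special.persistence_inequality == (special.value > 1)

    @given(st.floats(min_value=0.0, max_value=0.3),
           st.floats(min_value=0.0, max_value=0.3), bounded_rate)
    def test_case2_matches_general_formula(self, r1, k1, beta1):
        params = ModelParameters(r1=r1, k1=k1, beta1=beta1, alpha1=0.02,
                                 alpha2=0.03)
        special = r0_case2(params)
        general = r0_closed_form(params, 1000.0, 1000.0)
        assert special.value == pytest.approx(general.value, rel=1e-10)

    def test_case2_monotone_in_uptake_and_recidivism(self):
        grid = np.linspace(0.01, 0.2, 9)
        r0_k = [r0_case2(ModelParameters(k1=k, r1=0.05, beta1=0.1)).value
                for k in grid]
        r0_r = [r0_case2(ModelParameters(k1=0.05, r1=r, beta1=0.1)).value
                for r in grid]
        r0_b = [r0_case2(ModelParameters(k1=0.05, r1=0.05, beta1=b)).value
                for b in grid]
        assert np.all(np.diff(r0_k) > 0)
        assert np.all(np.diff(r0_r) > 0)
        assert np.all(np.diff(r0_b) < 0)


class TestNgm:
    def test_rejects_spontaneous_uptake(self):
        params = ModelParameters(gamma1=0.01, beta1=0.1, delta1=0.1,
                                 alpha1=0.1, delta2=0.1)
        with pytest.raises(DfeNotEquilibriumError):
            r0_ngm(params, 100.0, 100.0)

    def test_singular_transition_matrix_rejected(self):
        # no removal pathway at all: V = 0
        with pytest.raises(NonInvertibleTransitionError):
            r0_ngm(ModelParameters(r1=0.1), 100.0, 100.0)

    def test_zero_transmission_gives_zero_spectral_radius(self):
        params = ModelParameters(beta1=0.1, beta2=0.1, delta1=0.1, delta2=0.1)
        assert r0_ngm(params, 100.0, 100.0).value == 0.0

    def test_case2_sets_match_closed_form(self, fig3a_params, fig3b_params):
        for params in (fig3a_params, fig3b_params):
            expected = (params.k1 + params.r1) / params.beta1
            assert r0_ngm(params, 1000.0, 1000.0).value == pytest.approx(
                expected, rel=1e-10
            )

    def test_equivalence_with_closed_form_over_random_draws(self):
        # the module's central oracle property: spectral radius of F V^-1
        # equals the printed quadratic root
        rng = np.random.default_rng(20260919)
        for _ in range(300):
            draws = {name: rng.uniform(0.0, 0.3)
                     for name in ("r1", "r2", "k1", "k2", "beta1", "beta2")}
            draws.update({name: rng.uniform(0.01, 0.3)
                          for name in ("delta1", "delta2", "alpha1", "alpha2")})
            params = ModelParameters(**draws)
            s0 = rng.uniform(0.0, 1.0) * 1000.0
            ngm = r0_ngm(params, s0, 1000.0)
            closed = r0_closed_form(params, s0, 1000.0)
            assert ngm.value == pytest.approx(closed.value, rel=1e-8, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, Persistence.EXTINCTION),
            (0.999, Persistence.EXTINCTION),
            (1.0, Persistence.THRESHOLD),
            (1.0 + 5e-10, Persistence.THRESHOLD),
            (1.001, Persistence.PERSISTENCE),
            (2.0, Persistence.PERSISTENCE),
        ],
    )
    def test_threshold_bands(self, value, expected):
        assert classify_persistence(value) is expected

    @pytest.mark.parametrize("bad", [-0.5, float("nan"), float("inf")])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_persistence(bad)
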