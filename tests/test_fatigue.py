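"""Polynomial fitting, AIC order selection and inflection detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import archfatigue as af
from archfatigue.fatigue import aic


def test_exact_line_is_interpolated():
    c = np.arange(1, 12, dtype=float)
    fit = af.fit_polynomial(c, 2.0 + 3.0 * c, order=1)
    np.testing.assert_allclose(fit.coef, [2.0, 3.0], atol=1e-9)
    assert fit.se == pytest.approx(0.0, abs=1e-18)
    assert fit.r2 == pytest.approx(1.0)


def test_constant_series_r2_convention():
    c = np.arange(5, dtype=float)
    with pytest.warns(UserWarning, match="zero total variance"):
        fit = af.fit_polynomial(c, np.full(5, 0.2), order=2)
    assert fit.r2 == 1.0
    np.testing.assert_allclose(fit.coef[1:], 0.0, atol=1e-12)


def test_fit_matches_independent_normal_equations_solve():
    """Scaled-abscissa fit agrees with a brute-force normal-equations solve."""
    rng = np.random.default_rng(4)
    cycles = np.array(af.default_checkpoints(), dtype=float)
    truth = np.array([0.24, -2e-5, 3e-9, -2e-13])
    y = np.polynomial.polynomial.polyval(cycles, truth) + rng.normal(0, 5e-4, len(cycles))
    fit = af.fit_polynomial(cycles, y, order=3)
    x = cycles / cycles.max()  # independent, explicitly scaled design
    design = x[:, None] ** np.arange(4)
    beta_scaled = np.linalg.solve(design.T @ design, design.T @ y)
    beta = beta_scaled / cycles.max() ** np.arange(4)
    np.testing.assert_allclose(fit.coef, beta, rtol=1e-6)
    se = float(np.sum((y - design @ beta_scaled) ** 2))
    assert fit.se == pytest.approx(se, rel=1e-9)


def test_precondition_violations_rejected():
    with pytest.raises(ValueError, match="distinct"):
        af.fit_polynomial([1, 1, 2, 3], [0, 0, 1, 2], 1)
    with pytest.raises(ValueError, match="points"):
        af.fit_polynomial([1, 2, 3], [0, 1, 2], 3)


@given(
    n=st.integers(5, 200),
    se=st.floats(1e-8, 1e3),
    p=st.integers(1, 6),
)
def test_aic_formula_equivalence(n, se, p):
    """Reported AIC equals a from-scratch evaluation of the formula."""
    expected = n * (np.log(2.0 * np.pi * se / n) + 1.0) + 2.0 * (p + 1)
    assert aic(n, se, p) == pytest.approx(expected, rel=1e-12)


def test_zero_residual_aic_floored_with_warning():
    with pytest.warns(UserWarning, match="epsilon floor"):
        val = aic(10, 0.0, 3)
    assert np.isfinite(val)


def test_selection_prefers_true_order():
    rng = np.random.default_rng(11)
    c = np.arange(1, 101, dtype=float)
    linear = 1.0 - 0.01 * c + rng.normal(0, 0.01, len(c))
    assert af.aic_select(c, linear).selected_order == 1
    cubic = 1.0 - 0.01 * c + 1e-4 * c**2 - 7e-7 * c**3 + rng.normal(0, 0.01, len(c))
    assert af.aic_select(c, cubic).selected_order == 3


def test_single_candidate_and_duplicate_orders():
    c = np.arange(1, 12, dtype=float)
    y = 2.0 + 3.0 * c
    only = af.aic_select(c, y, orders=[4])
    assert only.selected_order == 4
    dup = af.aic_select(c, y, orders=[4, 4, 1])
    assert set(dup.fits) == {1, 4}


def test_analytic_inflection_of_cubic():
    # f(x) = x^3 - 3x^2: f'' = 6x - 6, root at 1
    roots = af.inflection_points([0.0, 0.0, -3.0, 1.0], (0.0, 2.0))
    np.testing.assert_allclose(roots, [1.0])
    assert af.primary_inflection([0.0, 0.0, 3.0, -1.0], (0.0, 2.0)) == pytest.approx(1.0)


def test_out_of_range_or_degenerate_inflection_is_none():
    assert len(af.inflection_points([0.0, 0.0, -3.0, 1.0], (2.0, 5.0))) == 0
    with pytest.warns(UserWarning, match="leading coefficient"):
        roots = af.inflection_points([1.0, -1.0, 0.0, 0.0], (0.0, 10.0))
    assert len(roots) == 0


def test_quartic_reports_all_inflections_ascending():
    # f'' of x^4 - 8x^2 is 12x^2 - 16: roots +-sqrt(4/3)
    roots = af.inflection_points([0.0, 0.0, -8.0, 0.0, 1.0], (-2.0, 2.0))
    expected = np.sqrt(4.0 / 3.0)
    np.testing.assert_allclose(roots, [-expected, expected], rtol=1e-9)


def test_fit_invariant_to_external_abscissa_scaling():
    """Predictions and inflection are unchanged when cycles are rescaled."""
    rng = np.random.default_rng(8)
    c = np.array(af.default_checkpoints(), dtype=float)
    y = 0.24 - 1e-5 * c + 2.4e-9 * c**2 - 1.6e-13 * c**3 + rng.normal(0, 3e-4, len(c))
    fit1 = af.aic_select(c, y, orders=[3])
    fit2 = af.aic_select(c / 1000.0, y, orders=[3])
    np.testing.assert_allclose(fit1.selected(c), fit2.selected(c / 1000.0), rtol=1e-8)
    assert fit1.inflection_cycle == pytest.approx(fit2.inflection_cycle * 1000.0, rel=1e-6)


def test_noise_free_pipeline_recovers_planted_cubic(noise_free_params):
    """Full round trip: planted coefficients and inflection to numerical precision."""
    p = noise_free_params
    trace = af.simulate_specimen(p, 2)
    m = af.cycle_metrics(af.segment_cycles(trace), trace.foot_length_mm)
    fit = af.aic_select(m["cycle"].to_numpy(), m["bai_wb"].to_numpy(), orders=[3])
    np.testing.assert_allclose(fit.selected.coef, p.trajectory_coef, rtol=1e-6, atol=1e-16)
    assert fit.inflection_cycle == pytest.approx(p.inflection_cycle, rel=1e-6)
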