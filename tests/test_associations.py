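"""2x2 statistics, table reconstruction, IRLS logistic, Kendall tau-b."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nssinet.associations import (
    AssociationError,
    ContingencyTable2x2,
    ModelSpec,
    SeparationError,
    association_strength_label,
    chi_square,
    crosstab,
    fit_logistic,
    fit_logistic_matrix,
    format_p,
    kendall_tau_b,
    odds_ratio_ci,
    reconstruct_two_by_two,
)
from nssinet.cohort import CohortTable


# ---------------------------------------------------------------------------
# chi-square and odds ratios


@pytest.mark.parametrize(
    "cells, expected_chi2",
    [
        ((32, 13, 15, 50), 25.072),
        ((1, 13, 46, 50), 8.301),
        ((20, 10, 27, 53), 9.660),
        ((5, 5, 5, 5), 0.0),
    ],
)
def test_chi_square_values(cells, expected_chi2):
    stat, p = chi_square(ContingencyTable2x2(*cells))
    assert stat == pytest.approx(expected_chi2, abs=5e-4)
    assert 0.0 <= p <= 1.0


def test_chi_square_zero_margin_is_an_error():
    with pytest.raises(AssociationError, match="zero margin"):
        chi_square(ContingencyTable2x2(0, 0, 5, 5))


@pytest.mark.parametrize(
    "cells, oratio, ci",
    [
        ((32, 13, 15, 50), 8.205, (3.454, 19.490)),
        ((20, 10, 27, 53), 3.926, (1.613, 9.554)),
        ((1, 13, 46, 50), 0.084, (0.011, 0.665)),
        ((1, 1, 1, 1), 1.0, None),
    ],
)
def test_odds_ratio_and_wald_ci(cells, oratio, ci):
    res = odds_ratio_ci(ContingencyTable2x2(*cells))
    assert res.odds_ratio == pytest.approx(oratio, abs=5e-4)
    if ci is not None:
        assert res.ci_low == pytest.approx(ci[0], abs=5e-4)
        assert res.ci_high == pytest.approx(ci[1], abs=5e-4)
    assert res.ci_low <= res.odds_ratio <= res.ci_high


def test_zero_cell_needs_haldane():
    table = ContingencyTable2x2(0, 10, 5, 5)
    with pytest.raises(AssociationError, match="haldane"):
        odds_ratio_ci(table)
    res = odds_ratio_ci(table, haldane=True)
    assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))


counts = st.integers(min_value=1, max_value=60)


@given(counts, counts, counts, counts)
def test_two_by_two_symmetries(a, b, c, d):
    """Transpose keeps chi2 and OR; swapping rows inverts the OR."""
    t = ContingencyTable2x2(a, b, c, d)
    transposed = ContingencyTable2x2(a, c, b, d)
    rows_swapped = ContingencyTable2x2(c, d, a, b)
    assert chi_square(t)[0] == pytest.approx(chi_square(transposed)[0], rel=1e-12)
    r = odds_ratio_ci(t)
    assert odds_ratio_ci(transposed).odds_ratio == pytest.approx(r.odds_ratio, rel=1e-12)
    assert odds_ratio_ci(rows_swapped).odds_ratio == pytest.approx(1.0 / r.odds_ratio, rel=1e-12)


def test_crosstab_counts_and_listwise_deletion(tiny_cohort):
    table = crosstab(tiny_cohort, ("anxiety_band", "severe"), ("suicide_high", "high"))
    # row with missing anxiety is dropped
    assert table.n == 2
    assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 1)


# ---------------------------------------------------------------------------
# table reconstruction


@pytest.mark.parametrize(
    "margin, printed, kind, cross, expected",
    [
        (45, 25.072, "chi_square", None, (32, 13, 15, 50)),
        (14, 0.084, "odds_ratio", ("chi_square", 8.301), (1, 13, 46, 50)),
        (30, 9.660, "chi_square", None, (20, 10, 27, 53)),
    ],
)
def test_reconstruction_recovers_the_unique_table(margin, printed, kind, cross, expected):
    table = reconstruct_two_by_two(
        exposure_margin=margin,
        n_candidates=range(108, 113),
        outcome_margin=47,
        printed_stat=printed,
        stat_kind=kind,
        cross_stat=cross,
    )
    assert (table.a, table.b, table.c, table.d) == expected
    assert table.n == 110


def test_reconstruction_rejects_ambiguity_and_no_match():
    with pytest.raises(AssociationError, match="ambiguous"):
        reconstruct_two_by_two(45, range(108, 113), 47, 5.0, "chi_square", tol=20.0)
    with pytest.raises(AssociationError, match="no table"):
        reconstruct_two_by_two(45, range(108, 113), 47, 1e6, "chi_square")


# ---------------------------------------------------------------------------
# logistic regression


def test_univariate_logistic_equals_table_odds_ratio():
    """A single binary predictor's fitted OR is the 2x2 OR (closed form)."""
    a, b, c, d = 32, 13, 15, 50
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_logistic_matrix(X, y, ["intercept", "exposure"])
    assert fit.converged
    assert math.exp(fit.coefficients[1]) == pytest.approx(a * d / (b * c), abs=1e-6)
    wald_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert fit.standard_errors[1] == pytest.approx(wald_se, abs=1e-6)


def test_irls_agrees_with_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    beta_true = np.array([-0.4, 0.8, -0.6])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    fit = fit_logistic_matrix(X, y, ["intercept", "x1", "x2"])
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)


def test_irls_recovers_known_coefficients_at_n5000():
    rng = np.random.default_rng(9)
    n = 5000
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
    beta_true = np.array([-1.0, 1.5, 0.5])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    fit = fit_logistic_matrix(X, y, ["intercept", "exposure", "age"])
    np.testing.assert_allclose(fit.coefficients, beta_true, atol=0.1)


def test_constant_outcome_and_separation_are_errors():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(AssociationError, match="constant"):
        fit_logistic_matrix(X, np.ones(10), ["intercept", "x"])
    y = (np.arange(10.0) >= 5).astype(float)  # perfectly separated
    with pytest.raises(SeparationError):
        fit_logistic_matrix(X, y, ["intercept", "x"])


def test_rank_deficient_design_names_columns():
    X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
    y = np.tile([0.0, 1.0], 10)
    with pytest.raises(AssociationError, match="collinear"):
        fit_logistic_matrix(X, y, ["intercept", "x", "x_doubled"])


def test_model_ladder_is_nested_and_fits_synthetic_cohort(cohort_112):
    spec1 = ModelSpec(("depression_band", "severe"), model=1)
    fit1 = fit_logistic(cohort_112, spec1)
    assert fit1.converged
    assert fit1.terms[:2] == ("intercept", "depression_band=severe")
    spec3 = ModelSpec(
        ("depression_band", "severe"), model=3, other_severe=("anxiety_band", "severe")
    )
    try:
        fit3 = fit_logistic(cohort_112, spec3)
        assert set(fit1.terms) < set(fit3.terms)
    except SeparationError:
        # legal on a 112-row cohort with rare covariate cells
        pass


# ---------------------------------------------------------------------------
# Kendall tau-b


def test_tau_examples():
    assert kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4]).tau_b == pytest.approx(1.0)
    assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]).tau_b == pytest.approx(-1.0)


def test_tau_on_binary_data_equals_phi():
    a, b, c, d = 32, 13, 15, 50
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    n = a + b + c + d
    chi2, _ = chi_square(ContingencyTable2x2(a, b, c, d))
    phi = math.copysign(math.sqrt(chi2 / n), a * d - b * c)
    assert kendall_tau_b(x, y).tau_b == pytest.approx(phi, abs=1e-12)


def _brute_force_tau_b(x, y):
    n = len(x)
    c_minus_d = sum(
        np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    n0 = n * (n - 1) / 2

    def ties(v):
        return sum(k * (k - 1) / 2 for k in np.unique(v, return_counts=True)[1])

    return c_minus_d / math.sqrt((n0 - ties(x)) * (n0 - ties(y)))


@given(
    st.lists(st.integers(0, 4), min_size=3, max_size=50).filter(
        lambda v: len(set(v)) > 1
    ),
    st.randoms(use_true_random=False),
)
def test_tau_matches_brute_force_pair_counting(xs, rnd):
    ys = [rnd.randint(0, 3) for _ in xs]
    if len(set(ys)) < 2:
        ys[0] = 1 + max(ys)
    x, y = np.array(xs, float), np.array(ys, float)
    assert kendall_tau_b(x, y).tau_b == pytest.approx(_brute_force_tau_b(x, y), abs=1e-12)


def test_tau_p_value_matches_scipy():
    from scipy.stats import kendalltau

    rng = np.random.default_rng(2)
    x = rng.integers(0, 3, 80).astype(float)
    y = (x + rng.integers(0, 2, 80)).astype(float)
    mine = kendall_tau_b(x, y)
    ref = kendalltau(x, y, variant="b")
    assert mine.tau_b == pytest.approx(ref.statistic, abs=1e-12)
    assert mine.p == pytest.approx(ref.pvalue, abs=1e-6)


def test_tau_constant_vector_is_an_error():
    with pytest.raises(AssociationError, match="constant"):
        kendall_tau_b([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# labels and formatting


@pytest.mark.parametrize(
    "coef, label",
    [
        (0.487, "moderate"),
        (0.15, "none"),
        (-0.85, "very strong"),
        (0.2, "none"),
        (0.2000001, "weak"),
        (0.8, "strong"),
        (1.0, "very strong"),
    ],
)
def test_association_strength_boundaries(coef, label):
    assert association_strength_label(coef) == label


def test_p_formatting():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.0376) == "0.038"
    assert format_p(0.5) == "0.500"
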