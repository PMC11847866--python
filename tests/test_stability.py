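"""Bootstrap stability, sensitivity, and the sample-size curve."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nssinet.cohort import CohortTable
from nssinet.network import threshold_adjacency
from nssinet.stability import (
    StabilityError,
    _isotonic,
    bootstrap_centralities,
    build_true_model,
    performance_statistic,
    recommend_sample_size,
    sensitivity,
)


# ---------------------------------------------------------------------------
# sensitivity and g


def test_sensitivity_counts_true_edges():
    true = np.array([[0, 1, 1, 0], [1, 0, 1, 1], [1, 1, 0, 0], [0, 1, 0, 0]])
    assert sensitivity(true, true).sen == 1.0
    half = true.copy()
    half[0, 1] = half[1, 0] = 0
    half[1, 3] = half[3, 1] = 0
    assert sensitivity(true, half).sen == 0.5
    assert sensitivity(true, np.zeros_like(true)).sen == 0.0


def test_sensitivity_undefined_without_true_edges():
    with pytest.raises(StabilityError, match="no edges"):
        sensitivity(np.zeros((3, 3), int), np.zeros((3, 3), int))


def test_performance_statistic_examples():
    assert performance_statistic([0.7, 0.5, 0.9], 0.6) == pytest.approx(2 / 3)
    assert performance_statistic([0.1, 0.2], 0.0) == 1.0
    # the boundary counts as success (gamma >= delta)
    assert performance_statistic([0.6], 0.6) == 1.0


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.floats(0, 1), st.floats(0, 1))
def test_performance_statistic_monotone_in_delta(gammas, d1, d2):
    lo, hi = min(d1, d2), max(d1, d2)
    assert performance_statistic(gammas, hi) <= performance_statistic(gammas, lo)


def test_isotonic_fit_is_nondecreasing_and_faithful():
    y = np.array([0.1, 0.3, 0.25, 0.6, 0.5, 0.9])
    fit = _isotonic(y)
    assert (np.diff(fit) >= -1e-12).all()
    np.testing.assert_allclose(fit, [0.1, 0.275, 0.275, 0.55, 0.55, 0.9])
    increasing = np.array([0.1, 0.2, 0.9])
    np.testing.assert_array_equal(_isotonic(increasing), increasing)


# ---------------------------------------------------------------------------
# true model


def test_true_model_density_and_threshold_consistency():
    model = build_true_model(4, 1.0, seed=0)
    assert model.adjacency.sum() // 2 == 6
    model10 = build_true_model(10, 0.3, seed=1)
    target_edges = round(0.3 * 45)
    assert abs(model10.adjacency.sum() // 2 - target_edges) <= 1
    np.testing.assert_array_equal(
        threshold_adjacency(model10.latent_correlation, 0.2), model10.adjacency
    )
    assert np.linalg.eigvalsh(model10.latent_correlation).min() > -1e-9


def test_true_model_rejects_bad_density():
    with pytest.raises(StabilityError):
        build_true_model(5, 0.0)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_deterministic_under_seed(cohort_112):
    a = bootstrap_centralities(cohort_112, B=25, seed=3)
    b = bootstrap_centralities(cohort_112, B=25, seed=3)
    np.testing.assert_array_equal(a.degree, b.degree)
    np.testing.assert_array_equal(a.betweenness, b.betweenness)
    c = bootstrap_centralities(cohort_112, B=25, seed=4)
    assert not np.array_equal(a.degree, c.degree)


def test_bootstrap_means_are_replicate_averages(cohort_112):
    summary = bootstrap_centralities(cohort_112, B=10, seed=1)
    np.testing.assert_allclose(summary.mean_degree, summary.degree.mean(axis=0))
    long = summary.long_table()
    assert len(long) == 10 * 25
    wide_mean = long.groupby("node", sort=False)["degree"].mean()
    np.testing.assert_allclose(
        wide_mean.to_numpy(), summary.mean_degree, atol=1e-12
    )


def test_single_row_cohort_bootstraps_to_itself(tiny_cohort):
    one = CohortTable(tiny_cohort.df.iloc[[0]].reset_index(drop=True))
    summary = bootstrap_centralities(one, B=1, seed=0)
    # n=1 resamples to the same row; every column constant -> empty network
    assert summary.degree.sum() == 0
    assert summary.betweenness.sum() == 0
    assert summary.zero_variance_replicates == 1


def test_identical_rows_give_empty_network_everywhere(tiny_cohort):
    df = pd.concat([tiny_cohort.df.iloc[[0]]] * 8, ignore_index=True)
    df["participant_id"] = [f"r{i}" for i in range(8)]
    summary = bootstrap_centralities(CohortTable(df), B=5, seed=2)
    assert (summary.degree == 0).all()
    assert (summary.betweenness == 0).all()
    assert summary.zero_variance_replicates == 5


def test_bootstrap_mean_degree_stabilises_with_B(cohort_112):
    small = bootstrap_centralities(cohort_112, B=150, seed=5)
    large = bootstrap_centralities(cohort_112, B=300, seed=6)
    assert np.abs(small.mean_degree - large.mean_degree).max() < 0.75


# ---------------------------------------------------------------------------
# sample-size curve


@pytest.fixture(scope="module")
def strong_model():
    """10-node model with clearly separated edge/non-edge correlations."""
    return build_true_model(10, 0.25, seed=7)


def test_delta_zero_recommends_first_grid_point(strong_model):
    result = recommend_sample_size(
        strong_model, delta=0.0, tau=0.8, R=5, n_grid=(50, 100), seed=0
    )
    assert result.recommended_n == 50


def test_unreachable_target_reports_not_reached(strong_model):
    result = recommend_sample_size(
        strong_model, delta=1.0, tau=1.0, R=10, n_grid=(10, 20), seed=0,
        node_model="binary",
    )
    assert result.recommended_n is None


def test_smoothed_curve_is_monotone_and_within_bounds(strong_model):
    result = recommend_sample_size(
        strong_model, delta=0.6, tau=0.8, R=20, n_grid=(50, 150, 300, 600), seed=1
    )
    assert (np.diff(result.g_smoothed) >= -1e-12).all()
    assert ((0.0 <= result.g) & (result.g <= 1.0)).all()
    assert result.curve_table().shape == (4, 3)


def test_gaussian_node_model_recovers_faster_than_binary(strong_model):
    gauss = recommend_sample_size(
        strong_model, R=15, n_grid=(100, 400), seed=2, node_model="gaussian"
    )
    binary = recommend_sample_size(
        strong_model, R=15, n_grid=(100, 400), seed=2, node_model="binary"
    )
    # dichotomising at the median attenuates correlations, so the binary
    # design can never beat the gaussian one on the same draws
    assert (gauss.g >= binary.g - 1e-12).all()


def test_grid_must_be_ascending(strong_model):
    with pytest.raises(StabilityError):
        recommend_sample_size(strong_model, n_grid=(200, 100), seed=0)
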