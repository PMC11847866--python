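"""Bootstrap stability of centralities and sensitivity-based sample size.

Two robustness tools around the correlation network:

* **Bootstrap stability** — resample participants with replacement
  (default B = 1000 replicates at the original n), rebuild the thresholded
  network per replicate and record each node's degree and betweenness;
  the per-node means across replicates summarise how stable the
  centrality ranking is.  Replicates routinely drop a rare category
  (e.g. the 4 divorce cases), making that indicator constant; such
  undefined correlations are set to 0 (no edge) and the affected
  replicate count is reported.

* **Sample-size recommendation** — fix a "true" network model (an
  adjacency plus a latent correlation matrix whose thresholding
  reproduces it), simulate R datasets at each candidate n, re-estimate
  the network and score the replicate by its sensitivity
  ``SEN = TP / (TP + FN)`` (the fraction of true edges recovered).  The
  performance statistic ``g = (1/R) sum_r [gamma_r >= delta]`` is the
  fraction of replicates reaching sensitivity ``delta``; the recommended
  sample size is the smallest candidate whose monotone-smoothed g reaches
  the probability threshold ``tau`` (defaults delta = 0.6, tau = 0.8:
  80% of replicates reach 60% sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, one_hot_encode
from .network import (
    betweenness_centrality,
    degree_centrality,
    network_density,
    pairwise_pearson,
    threshold_adjacency,
)


class StabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapSummary:
    B: int
    seed: int
    theta: float
    node_labels: tuple[str, ...]
    degree: np.ndarray  # B x p
    betweenness: np.ndarray  # B x p
    zero_variance_replicates: int

    @property
    def mean_degree(self) -> np.ndarray:
        return self.degree.mean(axis=0)

    @property
    def mean_betweenness(self) -> np.ndarray:
        return self.betweenness.mean(axis=0)

    def means_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.node_labels,
                "mean_degree": self.mean_degree,
                "mean_betweenness": self.mean_betweenness,
            }
        )

    def long_table(self) -> pd.DataFrame:
        """Per-replicate centralities in long format (replicate, node, ...)."""
        B, p = self.degree.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(1, B + 1), p),
                "node": list(self.node_labels) * B,
                "degree": self.degree.ravel(),
                "betweenness": self.betweenness.ravel(),
            }
        )


def _network_centralities(values: np.ndarray, theta: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Degree/betweenness of the thresholded network of a data matrix.

    Undefined correlations (zero-variance columns in this sample) count
    as r = 0; returns whether any column was degenerate.
    """
    r = pairwise_pearson(values)
    had_zero_variance = bool(np.isnan(r).any())
    adj = threshold_adjacency(np.nan_to_num(r, nan=0.0), theta)
    return degree_centrality(adj), betweenness_centrality(adj), had_zero_variance


def bootstrap_centralities(
    cohort: CohortTable,
    B: int = 1000,
    theta: float = 0.2,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap the thresholded-network centralities of a cohort.

    Each replicate resamples the n participants with replacement,
    re-encodes, recomputes pairwise correlations, thresholds at ``theta``
    and records per-node degree and betweenness.  Deterministic under
    ``seed``.
    """
    if B < 1:
        raise StabilityError("B must be >= 1")
    if cohort.n == 0:
        raise StabilityError("cohort is empty")
    encoded = one_hot_encode(cohort)
    values = encoded.values
    n, p = values.shape
    rng = np.random.default_rng(seed)
    degree = np.zeros((B, p), dtype=float)
    betweenness = np.zeros((B, p), dtype=float)
    n_degenerate = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        deg, bc, degen = _network_centralities(values[idx], theta)
        degree[b] = deg
        betweenness[b] = bc
        n_degenerate += degen
    return BootstrapSummary(
        B, seed, theta, tuple(encoded.column_labels), degree, betweenness, n_degenerate
    )


# ---------------------------------------------------------------------------
# Sensitivity and the performance statistic


@dataclass(frozen=True)
class SensitivityResult:
    tp: int
    fn: int

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn)


def sensitivity(true_adjacency: np.ndarray, estimated_adjacency: np.ndarray) -> SensitivityResult:
    """``SEN = TP / (TP + FN)`` over the true model's edge set."""
    t = np.asarray(true_adjacency)
    e = np.asarray(estimated_adjacency)
    if t.shape != e.shape:
        raise StabilityError("adjacency shapes differ")
    iu = np.triu_indices(t.shape[0], k=1)
    true_edges = t[iu] > 0
    if not true_edges.any():
        raise StabilityError("true model has no edges; sensitivity undefined")
    est_edges = e[iu] > 0
    tp = int((true_edges & est_edges).sum())
    fn = int((true_edges & ~est_edges).sum())
    return SensitivityResult(tp, fn)


def performance_statistic(gammas: np.ndarray, delta: float) -> float:
    """Fraction of replicate sensitivities meeting ``delta`` (inclusive)."""
    gammas = np.asarray(gammas, dtype=float)
    if gammas.size == 0:
        raise StabilityError("gammas must be non-empty")
    if not 0.0 <= delta <= 1.0:
        raise StabilityError("delta must be in [0, 1]")
    return float((gammas >= delta).mean())


# ---------------------------------------------------------------------------
# True model and the sample-size curve


@dataclass
class TrueModel:
    n_nodes: int
    adjacency: np.ndarray
    latent_correlation: np.ndarray

    @property
    def density(self) -> float:
        return network_density(self.n_nodes, int(self.adjacency.sum()) // 2)


def _nearest_correlation(matrix: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped, diagonally rescaled PSD correlation matrix."""
    vals, vecs = np.linalg.eigh(matrix)
    vals = np.clip(vals, eig_floor, None)
    s = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    np.fill_diagonal(s, 1.0)
    return 0.5 * (s + s.T)


def build_true_model(
    node_count: int,
    density_target: float,
    seed: int = 0,
    theta: float = 0.2,
    max_retries: int = 50,
) -> TrueModel:
    """Random true network whose latent correlations respect the threshold.

    Samples an adjacency with ``round(density N (N-1) / 2)`` edges
    uniformly, assigns edge correlations uniform in +/-[0.25, 0.6] and
    non-edge correlations in +/-[0, 0.15], projects to the nearest PSD
    correlation matrix, and verifies that thresholding recovers the
    adjacency exactly (resampling up to ``max_retries`` times).
    """
    if not 0.0 < density_target <= 1.0:
        raise StabilityError("density_target must be in (0, 1]")
    n_pairs = node_count * (node_count - 1) // 2
    n_edges = max(1, round(density_target * n_pairs))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(node_count, k=1)
    for _ in range(max_retries):
        edge_mask = np.zeros(n_pairs, dtype=bool)
        edge_mask[rng.choice(n_pairs, size=n_edges, replace=False)] = True
        weights = np.where(
            edge_mask,
            rng.uniform(0.25, 0.6, n_pairs),
            rng.uniform(0.0, 0.15, n_pairs),
        ) * rng.choice([-1.0, 1.0], n_pairs)
        latent = np.eye(node_count)
        latent[iu] = weights
        latent = latent + np.triu(latent, k=1).T
        latent = _nearest_correlation(latent)
        adjacency = np.zeros((node_count, node_count), dtype=int)
        adjacency[iu] = edge_mask
        adjacency = adjacency + adjacency.T
        if np.array_equal(threshold_adjacency(latent, theta), adjacency):
            return TrueModel(node_count, adjacency, latent)
    raise StabilityError(
        "could not build a true model whose PSD projection respects the "
        "threshold; widen the gap between edge and non-edge correlations"
    )


@dataclass
class SampleSizeResult:
    true_model: TrueModel
    delta: float
    tau: float
    R: int
    n_grid: tuple[int, ...]
    gammas: np.ndarray  # R x len(n_grid) per-replicate sensitivities
    g: np.ndarray  # raw g per candidate n
    g_smoothed: np.ndarray  # isotonic (non-decreasing) fit
    recommended_n: int | None  # None = "not reached"

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n_grid, "g": self.g, "g_smoothed": self.g_smoothed}
        )


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators non-decreasing fit (uniform weights)."""
    y = np.asarray(y, dtype=float)
    levels = list(y)
    counts = [1] * len(levels)
    i = 0
    while i < len(levels) - 1:
        if levels[i] > levels[i + 1] + 1e-15:
            merged = (levels[i] * counts[i] + levels[i + 1] * counts[i + 1]) / (
                counts[i] + counts[i + 1]
            )
            levels[i : i + 2] = [merged]
            counts[i : i + 2] = [counts[i] + counts[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    return np.repeat(levels, counts)


DEFAULT_N_GRID = tuple(range(100, 2001, 100))


def recommend_sample_size(
    true_model: TrueModel,
    delta: float = 0.6,
    tau: float = 0.8,
    R: int = 100,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    seed: int = 0,
    theta: float = 0.2,
    node_model: str = "binary",
    prevalences: np.ndarray | None = None,
) -> SampleSizeResult:
    """Monte-Carlo sample-size curve for recovering the true network.

    For each candidate n, R datasets are simulated from the true model's
    latent correlations — multivariate normal node scores, dichotomised
    at each node's quantile (median unless ``prevalences`` are given)
    when ``node_model='binary'``, or used as-is when ``'gaussian'`` —
    the network is re-estimated (Pearson correlation, threshold
    ``theta``), and the replicate's sensitivity against the true
    adjacency is recorded.  Common random numbers pair the candidates:
    each replicate draws one stream at the largest n and every candidate
    uses its leading rows, so the g-vs-n comparison is seed-paired.
    "Not reached" (``recommended_n = None``) is a legal outcome.
    """
    if list(n_grid) != sorted(n_grid) or len(n_grid) == 0:
        raise StabilityError("n_grid must be non-empty ascending")
    if R < 1:
        raise StabilityError("R must be >= 1")
    if node_model not in ("binary", "gaussian"):
        raise StabilityError("node_model must be 'binary' or 'gaussian'")
    p = true_model.n_nodes
    if prevalences is None:
        cuts = np.zeros(p)
    else:
        from scipy.stats import norm

        cuts = norm.ppf(1.0 - np.asarray(prevalences, dtype=float))
    chol = np.linalg.cholesky(
        true_model.latent_correlation + 1e-10 * np.eye(p)
    )
    rng = np.random.default_rng(seed)
    n_max = n_grid[-1]
    gammas = np.zeros((R, len(n_grid)))
    for r in range(R):
        z = rng.standard_normal((n_max, p)) @ chol.T
        x = (z > cuts).astype(float) if node_model == "binary" else z
        for k, n in enumerate(n_grid):
            sub = x[:n]
            with np.errstate(invalid="ignore", divide="ignore"):
                est_r = np.corrcoef(sub, rowvar=False)
            est_r = np.nan_to_num(est_r, nan=0.0)
            est_adj = threshold_adjacency(est_r, theta)
            gammas[r, k] = sensitivity(true_model.adjacency, est_adj).sen
    g = np.array([performance_statistic(gammas[:, k], delta) for k in range(len(n_grid))])
    g_smoothed = _isotonic(g)
    reached = np.flatnonzero(g_smoothed >= tau)
    recommended = int(n_grid[reached[0]]) if reached.size else None
    return SampleSizeResult(
        true_model, delta, tau, R, tuple(n_grid), gammas, g, g_smoothed, recommended
    )
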