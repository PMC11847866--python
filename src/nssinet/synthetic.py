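"""Synthetic cohort generator: a calibrated latent Gaussian copula.

No individual-level data were published for the study cohort, so every
downstream stage is exercised on synthetic cohorts that reproduce the
*published summaries*: the per-variable category prevalences, the
severe-depression/no-depression/severe-anxiety x high-suicide-risk joint
structure implied by the printed chi-square/OR pairs, and the significant
Kendall tau-b dependencies between symptom/self-concept/parental-education
indicators.

Generative model
----------------
Each categorical variable ``v`` is driven by one coordinate of a latent
multivariate normal vector with unit variances; the coordinate is cut at
the quantiles of the variable's target category prevalences, so marginals
are reproduced by construction.  Pairwise dependence targets (a 2x2 joint
table or a tau-b between two category indicators) pin down the latent
correlation of the two coordinates through the bivariate-normal rectangle
probability, which is monotone in the latent correlation — solved by
bisection.  Entries without a target are free; the full matrix is
completed to the nearest feasible positive semi-definite correlation
matrix with the calibrated entries held fixed, so calibrated targets are
preserved exactly whenever a PSD completion exists.

The high-suicide-risk flag is the one exception to the copula: its three
published 2x2 tables (against severe depression, no depression and severe
anxiety) over-determine a single latent correlation — no value of the
depression-suicide latent correlation reproduces both depression odds
ratios at once, because the observed risk profile across the four
depression bands is sharper than any bivariate-normal discretisation
allows.  The flag is therefore drawn from a calibrated conditional
Bernoulli response model ``P(high | dep band, anx band) =
sigmoid(alpha_dep + gamma [anx = severe])`` whose parameters are solved
against the three reconstructed conditional risks plus the overall
high-risk margin, with the (depression, anxiety) joint distribution taken
from the calibrated copula.  This reproduces all three tables' odds
ratios closely while leaving every other pairwise target untouched.

Age is drawn independently on 12..18; missingness is MCAR per variable.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import associations
from .cohort import VARIABLE_LEVELS, CohortTable, CSV_COLUMNS

#: Latent coordinate order (age handled separately).
LATENT_VARIABLES = tuple(VARIABLE_LEVELS)


class CalibrationError(ValueError):
    """A dependence target is infeasible for the given margins."""


# ---------------------------------------------------------------------------
# Targets


@dataclass(frozen=True)
class TauTarget:
    """Target Kendall tau-b between two category indicators.

    For binary indicators tau-b equals the phi coefficient, which fixes
    the joint cell probability given the two margins.
    """

    var_x: str
    cat_x: str
    var_y: str
    cat_y: str
    tau: float


@dataclass(frozen=True)
class JointTableTarget:
    """Target 2x2 cell probabilities for (var_x==cat_x) x (var_y==cat_y).

    ``cells`` are (a, b, c, d) probabilities in reading order with
    a = both indicators 1; they need not match the generator margins
    exactly (published tables and margins use slightly different
    denominators) — calibration matches the a-cell, or the log odds
    ratio when one latent pair carries several tables.
    """

    var_x: str
    cat_x: str
    var_y: str
    cat_y: str
    cells: tuple[float, float, float, float]

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self.cells
        return (a * d) / (b * c)


@dataclass(frozen=True)
class RiskResponseModel:
    """Conditional model of the high-suicide-risk flag.

    ``P(high | dep band d, anx band a) = sigmoid(alpha[d] + gamma [a == severe])``.
    Calibrated so the implied 2x2 tables against severe depression, no
    depression and severe anxiety, and the overall high-risk margin,
    match their targets.
    """

    alpha: dict[str, float]  # per depression band
    gamma_anx_severe: float

    def prob_high(self, dep_band: str, anx_band: str) -> float:
        eta = self.alpha[dep_band] + self.gamma_anx_severe * (anx_band == "severe")
        return 1.0 / (1.0 + math.exp(-eta))


@dataclass
class SyntheticConfig:
    n: int
    marginal_prevalences: dict[str, dict[str, float]]
    joint_tables: list[JointTableTarget]
    tau_targets: list[TauTarget]
    missing_rates: dict[str, float]
    age_distribution: dict[int, float]
    seed: int = 0
    latent_correlation: pd.DataFrame | None = None
    risk_model: RiskResponseModel | None = None
    with_minism_totals: bool = False

    def validate(self) -> None:
        for var, prev in self.marginal_prevalences.items():
            if set(prev) != set(VARIABLE_LEVELS[var]):
                raise ValueError(f"{var}: prevalence categories mismatch")
            if abs(sum(prev.values()) - 1.0) > 1e-9:
                raise ValueError(f"{var}: prevalences must sum to 1")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{var}: missing rate outside [0,1]")


@dataclass
class GeneratorReport:
    seed: int
    n: int
    realized_marginals: dict[str, dict[str, float]]
    realized_joint_tables: list[dict]
    realized_taus: list[dict]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n": self.n,
                    "realized_marginals": self.realized_marginals,
                    "realized_joint_tables": self.realized_joint_tables,
                    "realized_taus": self.realized_taus,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Study-default configuration

# Category counts from the published cohort of 112 (complete-case
# denominators where a variable has missing values).
_COUNTS = {
    "gender": {"male": 34, "female": 78},                      # /112
    "father_edu": {"primary": 51, "secondary": 28, "college_university": 33},  # /112
    "mother_edu": {"primary": 54, "secondary": 28, "college_university": 30},  # /112
    "income": {"lt_100k": 61, "100_250k": 35, "250_500k": 12, "gt_500k": 4},   # /112
    "quarrel": {"divorce": 4, "never": 24, "monthly_1_2": 56,
                "weekly_1_2": 19, "weekly_3_4_plus": 8},        # /111
    "depression_band": {"no": 14, "mild": 14, "moderate": 37, "severe": 45},   # /110
    "anxiety_band": {"no": 22, "mild": 28, "moderate": 30, "severe": 30},      # /110
    "self_concept": {"low": 101, "normal": 9},                  # /110
    "suicide_high": {"non_high": 64, "high": 47},               # /111
}

#: The reconstructed exposure x high-risk tables behind the published
#: chi-square/OR rows (recoverable from margins + the printed statistic by
#: exhaustive enumeration; all land at N = 110).
RECONSTRUCTED_TABLES = {
    ("depression_band", "severe"): (32, 13, 15, 50),
    ("depression_band", "no"): (1, 13, 46, 50),
    ("anxiety_band", "severe"): (20, 10, 27, 53),
}

_DEFAULT_MISSING = {
    "anxiety_band": 2 / 112,
    "quarrel": 1 / 112,
    "self_concept": 2 / 112,
    "suicide_high": 1 / 112,
}

#: Discrete age weights on 12..18 giving quartiles near 14 / 15.5 / 17.
_DEFAULT_AGE = {12: 0.06, 13: 0.12, 14: 0.15, 15: 0.16, 16: 0.17, 17: 0.18, 18: 0.16}


def default_paper_config(n: int = 112, seed: int = 0) -> SyntheticConfig:
    """Frozen study-condition defaults (uncalibrated; run
    :func:`calibrate_copula` before generating)."""
    marginals = {
        var: {cat: cnt / sum(cats.values()) for cat, cnt in cats.items()}
        for var, cats in _COUNTS.items()
    }
    joint = [
        JointTableTarget(var, cat, "suicide_high", "high",
                         tuple(v / sum(cells) for v in cells))
        for (var, cat), cells in RECONSTRUCTED_TABLES.items()
    ]
    taus = [
        TauTarget("depression_band", "severe", "anxiety_band", "severe", 0.487),
        # tau is taken against the low-self-concept indicator: the study
        # reports low self-concept as positively associated with severe
        # depression (no severe-depression case had normal self-concept).
        TauTarget("depression_band", "severe", "self_concept", "low", 0.248),
        TauTarget("anxiety_band", "severe", "father_edu", "college_university", 0.327),
    ]
    cfg = SyntheticConfig(
        n=n,
        marginal_prevalences=marginals,
        joint_tables=joint,
        tau_targets=taus,
        missing_rates=dict(_DEFAULT_MISSING),
        age_distribution=dict(_DEFAULT_AGE),
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Copula calibration


def _thresholds(prevalences: dict[str, float], var: str) -> np.ndarray:
    """Interior latent cut points of a variable (category order fixed)."""
    levels = VARIABLE_LEVELS[var]
    probs = np.array([prevalences[lev] for lev in levels])
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(cum)


def _category_interval(
    prevalences: dict[str, float], var: str, cat: str
) -> tuple[float, float]:
    """Latent interval (lo, hi) mapped to a category."""
    levels = VARIABLE_LEVELS[var]
    cuts = np.concatenate([[-np.inf], _thresholds(prevalences, var), [np.inf]])
    k = levels.index(cat)
    return float(cuts[k]), float(cuts[k + 1])


def bvn_rectangle(lo: tuple[float, float], hi: tuple[float, float], rho: float) -> float:
    """P(lo1 < Z1 < hi1, lo2 < Z2 < hi2) for standard bivariate normal."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    return float(mvn.cdf(np.array(hi), lower_limit=np.array(lo)))


def _pair_cell_prob(
    prevalences: dict[str, dict[str, float]],
    var_x: str, cat_x: str, var_y: str, cat_y: str, rho: float,
) -> float:
    lox, hix = _category_interval(prevalences[var_x], var_x, cat_x)
    loy, hiy = _category_interval(prevalences[var_y], var_y, cat_y)
    return bvn_rectangle((lox, loy), (hix, hiy), rho)


def solve_latent_rho(
    cell_fn: Callable[[float], float],
    target: float,
    tol: float = 1e-10,
    bound: float = 0.9995,
    pair_name: str = "",
) -> float:
    """Bisection for the latent correlation matching a cell probability.

    ``cell_fn`` must be monotone in rho (true when both indicator
    intervals are one-sided tails, as for all study targets)."""
    lo_val, hi_val = cell_fn(-bound), cell_fn(bound)
    increasing = hi_val >= lo_val
    lo_v, hi_v = (lo_val, hi_val) if increasing else (hi_val, lo_val)
    if not (lo_v - 1e-9 <= target <= hi_v + 1e-9):
        raise CalibrationError(
            f"target cell probability {target:.4f} for pair {pair_name} outside "
            f"attainable range [{lo_v:.4f}, {hi_v:.4f}]"
        )
    a, b = -bound, bound
    for _ in range(80):
        mid = 0.5 * (a + b)
        v = cell_fn(mid)
        if (v < target) == increasing:
            a = mid
        else:
            b = mid
        if b - a < tol:
            break
    return 0.5 * (a + b)


def _tau_to_cell(
    prevalences: dict[str, dict[str, float]], t: TauTarget
) -> float:
    """Joint cell probability implied by a tau-b target on two binaries."""
    px = prevalences[t.var_x][t.cat_x]
    py = prevalences[t.var_y][t.cat_y]
    scale = math.sqrt(px * (1 - px) * py * (1 - py))
    cell = px * py + t.tau * scale
    lo_bound = max(0.0, px + py - 1.0)
    hi_bound = min(px, py)
    if not (lo_bound - 1e-9 <= cell <= hi_bound + 1e-9):
        max_tau = (hi_bound - px * py) / scale
        min_tau = (lo_bound - px * py) / scale
        raise CalibrationError(
            f"tau target {t.tau} for ({t.var_x}={t.cat_x}, {t.var_y}={t.cat_y}) "
            f"infeasible for margins ({px:.3f}, {py:.3f}); attainable tau in "
            f"[{min_tau:.3f}, {max_tau:.3f}]"
        )
    return cell


def _psd_complete_fixed(
    matrix: np.ndarray, fixed: np.ndarray, max_iter: int = 2000, eig_floor: float = 1e-7
) -> np.ndarray:
    """PSD correlation completion holding ``fixed`` entries in place.

    Alternating projections: clip eigenvalues, then restore the unit
    diagonal and the fixed (calibrated) entries.  Converges to a PSD
    matrix with the fixed entries intact whenever one exists; otherwise
    returns the best compromise after ``max_iter`` sweeps (fixed entries
    then re-imposed only to numerical tolerance)."""
    s = matrix.copy()
    target = matrix.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(s)
        if vals.min() >= eig_floor / 10:
            break
        vals = np.clip(vals, eig_floor, None)
        s = (vecs * vals) @ vecs.T
        np.fill_diagonal(s, 1.0)
        s[fixed] = target[fixed]
        s = 0.5 * (s + s.T)
    return s


def calibrate_copula(config: SyntheticConfig) -> SyntheticConfig:
    """Solve the latent correlation matrix from the dependence targets.

    Tables whose outcome is the high-suicide-risk flag (exposures in the
    depression or anxiety bands) calibrate the conditional risk response
    model; any other joint-table target pins its latent pair directly and
    wins over a tau target on the same pair.  Free entries default to 0
    and are then adjusted by the fixed-entry PSD completion.
    """
    config = copy.deepcopy(config)
    config.validate()
    p = len(LATENT_VARIABLES)
    idx = {v: i for i, v in enumerate(LATENT_VARIABLES)}
    corr = np.eye(p)
    fixed = np.zeros((p, p), dtype=bool)
    prev = config.marginal_prevalences

    risk_tables = [
        t for t in config.joint_tables
        if t.var_y == "suicide_high"
        and t.var_x in ("depression_band", "anxiety_band")
    ]
    copula_tables = [t for t in config.joint_tables if t not in risk_tables]

    for t in copula_tables:
        i, j = sorted((idx[t.var_x], idx[t.var_y]))
        fn = lambda rho, t=t: _pair_cell_prob(prev, t.var_x, t.cat_x, t.var_y, t.cat_y, rho)
        rho = solve_latent_rho(fn, t.cells[0], pair_name=f"{t.var_x}x{t.var_y}")
        corr[i, j] = corr[j, i] = rho
        fixed[i, j] = fixed[j, i] = True

    for t in config.tau_targets:
        i, j = sorted((idx[t.var_x], idx[t.var_y]))
        if fixed[i, j]:
            continue  # joint table wins; tau is reported, not enforced
        cell = _tau_to_cell(prev, t)
        fn = lambda rho, t=t: _pair_cell_prob(prev, t.var_x, t.cat_x, t.var_y, t.cat_y, rho)
        rho = solve_latent_rho(fn, cell, pair_name=f"{t.var_x}x{t.var_y}")
        corr[i, j] = corr[j, i] = rho
        fixed[i, j] = fixed[j, i] = True

    corr = _psd_complete_fixed(corr, fixed)
    vals = np.linalg.eigvalsh(corr)
    if vals.min() < -1e-8:
        raise CalibrationError(
            f"could not complete a PSD latent matrix (min eigenvalue {vals.min():.2e})"
        )
    config.latent_correlation = pd.DataFrame(
        corr, index=list(LATENT_VARIABLES), columns=list(LATENT_VARIABLES)
    )
    if risk_tables:
        config.risk_model = _solve_risk_model(config, risk_tables)
    return config


def _dep_anx_joint(config: SyntheticConfig) -> np.ndarray:
    """4x4 joint band probabilities of (depression, anxiety) under the copula."""
    assert config.latent_correlation is not None
    rho = float(config.latent_correlation.loc["depression_band", "anxiety_band"])
    prev = config.marginal_prevalences
    dep_levels = VARIABLE_LEVELS["depression_band"]
    anx_levels = VARIABLE_LEVELS["anxiety_band"]
    joint = np.zeros((len(dep_levels), len(anx_levels)))
    for i, d in enumerate(dep_levels):
        lod, hid = _category_interval(prev["depression_band"], "depression_band", d)
        for j, a in enumerate(anx_levels):
            loa, hia = _category_interval(prev["anxiety_band"], "anxiety_band", a)
            joint[i, j] = bvn_rectangle((lod, loa), (hid, hia), rho)
    return joint / joint.sum()


def _solve_risk_model(
    config: SyntheticConfig, risk_tables: list[JointTableTarget]
) -> RiskResponseModel:
    """Solve (alpha_no, alpha_mid, alpha_severe, gamma) for the risk flag.

    Matches the conditional high-risk probabilities implied by each target
    table plus the configured overall high-risk margin; the mild and
    moderate depression bands share one baseline (the published analysis
    only distinguishes the no / severe extremes).
    """
    from scipy.optimize import least_squares

    joint = _dep_anx_joint(config)
    dep_levels = list(VARIABLE_LEVELS["depression_band"])
    anx_levels = list(VARIABLE_LEVELS["anxiety_band"])
    margin_high = config.marginal_prevalences["suicide_high"]["high"]

    # target conditional P(high | indicator): a / (a + b) of each table
    cond_targets: list[tuple[str, str, float]] = []
    for t in risk_tables:
        cond_targets.append((t.var_x, t.cat_x, t.cells[0] / (t.cells[0] + t.cells[1])))

    def unpack(x: np.ndarray) -> RiskResponseModel:
        alpha = {
            "no": x[0], "mild": x[1], "moderate": x[1], "severe": x[2],
        }
        return RiskResponseModel(alpha, x[3])

    def residuals(x: np.ndarray) -> np.ndarray:
        model = unpack(x)
        probs = np.array(
            [[model.prob_high(d, a) for a in anx_levels] for d in dep_levels]
        )
        res = []
        for var, cat, target in cond_targets:
            if var == "depression_band":
                i = dep_levels.index(cat)
                implied = (joint[i] * probs[i]).sum() / joint[i].sum()
            else:
                j = anx_levels.index(cat)
                implied = (joint[:, j] * probs[:, j]).sum() / joint[:, j].sum()
            res.append(implied - target)
        res.append((joint * probs).sum() - margin_high)
        return np.array(res)

    x0 = np.array([-2.5, -0.5, 0.9, 0.5])
    sol = least_squares(residuals, x0, method="lm")
    if not sol.success or np.max(np.abs(sol.fun)) > 5e-3:
        raise CalibrationError(
            f"risk-model calibration failed (max residual {np.max(np.abs(sol.fun)):.4f})"
        )
    return unpack(sol.x)


# ---------------------------------------------------------------------------
# Generation


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, GeneratorReport]:
    """Draw a cohort from a calibrated config; deterministic under seed."""
    if config.latent_correlation is None:
        raise CalibrationError("config has no latent correlation; run calibrate_copula first")
    corr = config.latent_correlation.to_numpy()
    vals = np.linalg.eigvalsh(corr)
    if vals.min() < -1e-8:
        raise CalibrationError("latent matrix not PSD; run calibrate_copula first")
    # tiny jitter for numerically semi-definite matrices
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    rng = np.random.default_rng(config.seed)
    n = config.n
    z = rng.standard_normal((n, corr.shape[0])) @ chol.T

    df = pd.DataFrame({"participant_id": [f"P{i + 1:05d}" for i in range(n)]})
    ages = np.array(sorted(config.age_distribution))
    aw = np.array([config.age_distribution[a] for a in ages], dtype=float)
    df["age"] = rng.choice(ages, size=n, p=aw / aw.sum()).astype(float)

    for k, var in enumerate(LATENT_VARIABLES):
        if var == "suicide_high" and config.risk_model is not None:
            continue
        cuts = _thresholds(config.marginal_prevalences[var], var)
        codes = np.searchsorted(cuts, z[:, k])
        levels = VARIABLE_LEVELS[var]
        df[var] = pd.Series([levels[c] for c in codes], dtype=object)

    if config.risk_model is not None:
        probs = np.array(
            [
                config.risk_model.prob_high(d, a)
                for d, a in zip(df["depression_band"], df["anxiety_band"])
            ]
        )
        df["suicide_high"] = np.where(rng.random(n) < probs, "high", "non_high")
        df["suicide_high"] = df["suicide_high"].astype(object)

    minism = None
    if config.with_minism_totals:
        # totals drawn uniformly within the band implied by the risk flag
        high = (df["suicide_high"] == "high").to_numpy()
        minism = np.where(high, rng.integers(17, 53, size=n), rng.integers(0, 17, size=n))

    for var, rate in config.missing_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, var] = np.nan

    if minism is not None:
        df["minism_total"] = minism

    cohort = CohortTable(df[list(CSV_COLUMNS)])
    if minism is not None:
        cohort.df["minism_total"] = minism
    report = _generator_report(cohort, config)
    return cohort, report


def _generator_report(cohort: CohortTable, config: SyntheticConfig) -> GeneratorReport:
    realized_marg = {}
    for var in LATENT_VARIABLES:
        col = cohort.df[var].dropna()
        realized_marg[var] = {
            lev: float((col == lev).mean()) if len(col) else math.nan
            for lev in VARIABLE_LEVELS[var]
        }
    tables = []
    for t in config.joint_tables:
        tab = associations.crosstab(cohort, (t.var_x, t.cat_x), (t.var_y, t.cat_y))
        tables.append(
            {
                "pair": [f"{t.var_x}={t.cat_x}", f"{t.var_y}={t.cat_y}"],
                "target_cells": list(t.cells),
                "realized_counts": [tab.a, tab.b, tab.c, tab.d],
                "target_odds_ratio": t.odds_ratio,
                "realized_odds_ratio": (
                    (tab.a * tab.d) / (tab.b * tab.c) if tab.b * tab.c > 0 else None
                ),
            }
        )
    taus = []
    from .cohort import indicator

    for t in config.tau_targets:
        x = indicator(cohort, t.var_x, t.cat_x)
        y = indicator(cohort, t.var_y, t.cat_y)
        try:
            res = associations.kendall_tau_b(x, y)
            realized = res.tau_b
        except associations.AssociationError:
            realized = math.nan
        taus.append(
            {
                "pair": [f"{t.var_x}={t.cat_x}", f"{t.var_y}={t.cat_y}"],
                "target_tau": t.tau,
                "realized_tau": realized,
            }
        )
    return GeneratorReport(config.seed, cohort.n, realized_marg, tables, taus)
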