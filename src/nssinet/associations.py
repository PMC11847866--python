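"""Association statistics: 2x2 tables, logistic models, Kendall tau-b.

This layer reproduces the study's association analyses:

* Pearson chi-square (1 df, uncorrected) and odds ratios with Wald 95%
  confidence intervals for exposure x high-suicide-risk 2x2 tables.
* Exhaustive reconstruction of unpublished 2x2 tables from printed
  marginals and a printed statistic — the joint tables behind the
  published chi-square/OR pairs are never printed, but with row and
  column margins fixed the integer tables can be enumerated and the
  unique match recovered.
* Maximum-likelihood logistic regression via iteratively reweighted
  least squares (IRLS), with the Model 1/2/3 covariate ladder
  (age+gender; + parental education, income, quarrel frequency; + the
  other symptom's severe indicator).
* Kendall tau-b rank correlation with tie-corrected variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VARIABLE_LEVELS, CohortTable, indicator

Z_95 = 1.959964  # two-sided 95% normal quantile


class AssociationError(ValueError):
    """Statistic undefined for the given table or data."""


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = exposure (present/absent), cols = event (yes/no).

    ``a`` = exposed & event, ``b`` = exposed & no event,
    ``c`` = unexposed & event, ``d`` = unexposed & no event.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AssociationError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    chi_square: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2


def crosstab(
    cohort: CohortTable,
    exposure: tuple[str, str],
    outcome: tuple[str, str],
) -> ContingencyTable2x2:
    """2x2 cross-tabulation of two (variable, category) indicators.

    Rows with either variable missing are dropped (listwise on the pair).
    """
    x = indicator(cohort, *exposure)
    y = indicator(cohort, *outcome)
    ok = ~(x.isna() | y.isna())
    x = x[ok].astype(int)
    y = y[ok].astype(int)
    return ContingencyTable2x2(
        a=int(((x == 1) & (y == 1)).sum()),
        b=int(((x == 1) & (y == 0)).sum()),
        c=int(((x == 0) & (y == 1)).sum()),
        d=int(((x == 0) & (y == 0)).sum()),
    )


def chi_square(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) and its p-value.

    ``chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; any zero margin
    leaves the statistic undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise AssociationError("chi-square undefined: zero margin")
    stat = table.n * (a * d - b * c) ** 2 / math.prod(margins)
    return stat, float(stats.chi2.sf(stat, df=1))


def odds_ratio_ci(
    table: ContingencyTable2x2,
    level: float = 0.95,
    haldane: bool = False,
) -> AssociationResult:
    """Odds ratio ad/(bc) with Wald confidence interval.

    ``CI = exp(ln OR +/- z sqrt(1/a + 1/b + 1/c + 1/d))``.  Zero cells
    are an error by default; ``haldane=True`` adds 0.5 to every cell
    (Haldane–Anscombe) instead.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise AssociationError(
                "odds ratio undefined with a zero cell; pass haldane=True "
                "for the 0.5-corrected estimate"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = stats.norm.ppf(0.5 + level / 2) if level != 0.95 else Z_95
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(oratio) - z * se), math.exp(math.log(oratio) + z * se)
    chi2_stat, p = chi_square(table)
    return AssociationResult(chi2_stat, p, oratio, lo, hi, table)


def reconstruct_two_by_two(
    exposure_margin: int,
    n_candidates: Sequence[int],
    outcome_margin: int,
    printed_stat: float,
    stat_kind: str = "chi_square",
    tol: float = 5e-4,
    cross_stat: tuple[str, float] | None = None,
) -> ContingencyTable2x2:
    """Recover an unpublished 2x2 table from margins and a printed statistic.

    Enumerates every integer table with row sums ``(m, N - m)`` over
    ``N in n_candidates`` and column sums ``(s, N - s)`` for ``s`` within
    one of ``outcome_margin``, and returns the unique table whose
    statistic (``chi_square`` or ``odds_ratio``) matches ``printed_stat``
    within ``tol``.  The default tolerance is half an ulp of a value
    printed to three decimals, i.e. the table must reproduce the printed
    statistic exactly at the printed precision.  Zero or multiple matches
    raise, listing near misses.

    A row printed with several statistics may be ambiguous on one alone
    (different N can give the same 3-dp odds ratio); ``cross_stat`` =
    ``(kind, value)`` additionally requires the second statistic to match
    at the same precision, disambiguating without circularity.
    """
    if stat_kind not in ("chi_square", "odds_ratio"):
        raise ValueError(f"unknown stat_kind {stat_kind!r}")

    def _stat(table: ContingencyTable2x2, kind: str) -> float | None:
        if kind == "chi_square":
            return chi_square(table)[0]
        if table.b == 0 or table.c == 0:
            return None
        return (table.a * table.d) / (table.b * table.c)
    matches: list[ContingencyTable2x2] = []
    near: list[tuple[float, ContingencyTable2x2]] = []
    for n_total in n_candidates:
        m = exposure_margin
        for s in range(outcome_margin - 1, outcome_margin + 2):
            if not (0 < s < n_total and 0 < m < n_total):
                continue
            for a in range(max(0, m + s - n_total), min(m, s) + 1):
                b, c = m - a, s - a
                d = n_total - m - s + a
                table = ContingencyTable2x2(a, b, c, d)
                try:
                    value = _stat(table, stat_kind)
                except AssociationError:
                    continue
                if value is None:
                    continue
                err = abs(value - printed_stat)
                if err <= tol:
                    if cross_stat is not None:
                        try:
                            other = _stat(table, cross_stat[0])
                        except AssociationError:
                            continue
                        if other is None or abs(other - cross_stat[1]) > tol:
                            continue
                    matches.append(table)
                elif err <= 50 * tol:
                    near.append((err, table))
    if len(matches) == 1:
        return matches[0]
    if not matches:
        near.sort(key=lambda t: t[0])
        raise AssociationError(
            f"no table matches {stat_kind}={printed_stat} within {tol}; "
            f"nearest misses: {[(round(e, 4), t) for e, t in near[:3]]}"
        )
    raise AssociationError(
        f"ambiguous reconstruction: {len(matches)} tables match "
        f"{stat_kind}={printed_stat} within {tol}: {matches}"
    )


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)


class SeparationError(RuntimeError):
    """The likelihood is unbounded (quasi-)separation detected."""


@dataclass
class LogisticFit:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    n_used: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def conf_int(self, z: float = Z_95) -> np.ndarray:
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )


def fit_logistic_matrix(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str],
    max_iter: int = 50,
    score_tol: float = 1e-8,
    beta_bound: float = 15.0,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS on a prepared design.

    ``X`` must include the intercept column.  Convergence when the score
    (gradient) has max absolute value below ``score_tol``.  Diverging
    coefficients (|beta| > ``beta_bound``) raise :class:`SeparationError`;
    a rank-deficient design raises naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise AssociationError(f"too few rows ({n}) for {p} terms")
    if len(set(np.unique(y)) - {0.0, 1.0}) > 0:
        raise AssociationError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise AssociationError("outcome is constant; model undefined")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[-1])
        cols = [terms[i] for i in np.flatnonzero(null > 0.3)]
        raise AssociationError(f"rank-deficient design; collinear columns: {cols}")
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > beta_bound:
            big = [terms[i] for i in np.flatnonzero(np.abs(beta) > beta_bound)]
            raise SeparationError(
                f"coefficients diverging (|beta| > {beta_bound}) for {big}; "
                "likely perfect separation"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(tuple(terms), beta, se, converged, it, n)


#: Reference categories dropped when a multi-category variable enters a model.
REFERENCE_CATEGORIES = {
    "father_edu": "primary",
    "mother_edu": "primary",
    "income": "lt_100k",
    "quarrel": "never",
}

MODEL2_COVARIATES = ("father_edu", "mother_edu", "income", "quarrel")


@dataclass(frozen=True)
class ModelSpec:
    """Exposure indicator plus the Model 1/2/3 adjustment ladder.

    Model 1 adjusts for age and gender; Model 2 adds parental education,
    income and quarrel frequency (dummy-coded against the reference
    categories); Model 3 adds the other symptom's severe indicator.
    """

    exposure: tuple[str, str]  # e.g. ("depression_band", "severe")
    model: int = 1
    other_severe: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        if self.model == 3 and self.other_severe is None:
            raise ValueError("Model 3 requires other_severe")


def build_design(
    cohort: CohortTable,
    spec: ModelSpec,
    outcome: tuple[str, str] = ("suicide_high", "high"),
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Listwise-complete design matrix for a :class:`ModelSpec`.

    Returns ``(X, y, terms, n_used)`` with an intercept column first and
    the exposure indicator second.
    """
    cols: dict[str, pd.Series] = {}
    cols[f"{spec.exposure[0]}={spec.exposure[1]}"] = indicator(cohort, *spec.exposure)
    cols["age"] = cohort.df["age"]
    cols["gender=female"] = indicator(cohort, "gender", "female")
    if spec.model >= 2:
        for var in MODEL2_COVARIATES:
            ref = REFERENCE_CATEGORIES[var]
            for lev in VARIABLE_LEVELS[var]:
                if lev != ref:
                    cols[f"{var}={lev}"] = indicator(cohort, var, lev)
    if spec.model == 3:
        assert spec.other_severe is not None
        cols[f"{spec.other_severe[0]}={spec.other_severe[1]}"] = indicator(
            cohort, *spec.other_severe
        )
    y = indicator(cohort, *outcome)
    frame = pd.DataFrame(cols)
    frame["_y"] = y
    frame = frame.dropna()
    terms = ["intercept"] + list(cols)
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy() for c in cols])
    return X, frame["_y"].to_numpy(), terms, len(frame)


def fit_logistic(cohort: CohortTable, spec: ModelSpec, **kwargs) -> LogisticFit:
    """Fit an adjusted logistic model of high suicide risk on a cohort."""
    X, y, terms, _ = build_design(cohort, spec)
    return fit_logistic_matrix(X, y, terms, **kwargs)


# ---------------------------------------------------------------------------
# Kendall tau-b


@dataclass(frozen=True)
class KendallResult:
    tau_b: float
    p: float
    n_pairs_used: int


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> KendallResult:
    """Kendall tau-b with tie correction and normal-approximation p-value.

    ``tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))`` where ``C``/``D`` count
    concordant/discordant pairs, ``n0 = n(n-1)/2`` and ``n1``/``n2`` are
    the tie sums of each variable.  The p-value uses the tie-adjusted
    variance of ``C - D`` under independence.  Pairs with a missing value
    in either vector are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise AssociationError("need at least 2 pairwise-complete observations")
    xu, xinv = np.unique(x, return_inverse=True)
    yu, yinv = np.unique(y, return_inverse=True)
    if xu.size < 2 or yu.size < 2:
        raise AssociationError("tau-b undefined for a constant vector")
    if xu.size * yu.size <= 4_000_000:
        # concordance counts from the contingency table: for each cell,
        # pair it once with every cell strictly below-left (concordant)
        # or below-right (discordant)
        table = np.zeros((xu.size, yu.size))
        np.add.at(table, (xinv, yinv), 1.0)
        cum = table.cumsum(axis=0).cumsum(axis=1)  # cum[i,j] = sum_{k<=i, l<=j}
        below_left = np.zeros_like(table)
        below_left[1:, 1:] = cum[:-1, :-1]
        below_right = np.zeros_like(table)
        below_right[1:, :] = cum[:-1, -1:] - cum[:-1, :]
        concordant = float((table * below_left).sum())
        discordant = float((table * below_right).sum())
        c_minus_d = concordant - discordant
    elif n <= 20_000:
        dx = np.sign(x[:, None] - x[None, :])
        dy = np.sign(y[:, None] - y[None, :])
        iu = np.triu_indices(n, k=1)
        c_minus_d = float((dx[iu] * dy[iu]).sum())
    else:
        raise AssociationError(
            "tau-b on large near-continuous vectors is not supported; "
            "bin the data first"
        )
    n0 = n * (n - 1) / 2

    def tie_sums(v: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(v, return_counts=True)
        t = counts.astype(float)
        return (
            float((t * (t - 1) / 2).sum()),
            float((t * (t - 1) * (2 * t + 5)).sum()),
            float((t * (t - 1) * (t - 2)).sum()),
        )

    n1, vt, t3x = tie_sums(x)
    n2, vu, t3y = tie_sums(y)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = c_minus_d / denom
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - vt - vu) / 18.0
    var += (2 * n1) * (2 * n2) / (2.0 * n * (n - 1))
    var += t3x * t3y / (9.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
    z = c_minus_d / math.sqrt(var) if var > 0 else 0.0
    p = 2 * float(stats.norm.sf(abs(z)))
    return KendallResult(tau, min(p, 1.0), n)


def kendall_matrix(columns: dict[str, Sequence[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tau-b matrix (and p-values) over named ordinal vectors."""
    names = list(columns)
    k = len(names)
    taus = np.eye(k)
    ps = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        res = kendall_tau_b(columns[names[i]], columns[names[j]])
        taus[i, j] = taus[j, i] = res.tau_b
        ps[i, j] = ps[j, i] = res.p
    return (
        pd.DataFrame(taus, index=names, columns=names),
        pd.DataFrame(ps, index=names, columns=names),
    )


#: Correlation-strength bands (lower-exclusive, upper-inclusive on |coef|).
_STRENGTH_BOUNDS = ((0.2, "none"), (0.4, "weak"), (0.6, "moderate"), (0.8, "strong"))


def association_strength_label(coefficient: float) -> str:
    """Verbal strength of a correlation coefficient.

    |coef| in [0, .2] none, (.2, .4] weak, (.4, .6] moderate,
    (.6, .8] strong, (.8, 1] very strong.
    """
    a = abs(coefficient)
    if a > 1:
        raise ValueError("|coefficient| must be <= 1")
    for bound, label in _STRENGTH_BOUNDS:
        if a <= bound:
            return label
    return "very strong"


def format_p(p: float) -> str:
    """p to 3 decimals, '<0.001' below that (report style)."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
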