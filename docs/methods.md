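# Methods

This note documents the statistical procedures implemented in `nssinet`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Instruments and banding

* **MINISM** (suicidality module): total 0–52; bands 0 / 1–8 / 9–16 /
  ≥ 17 (absence / low / moderate / high). The binary analysis flag is
  `total >= 17`.
* **SDS / SAS** (Zung depression/anxiety): 20 items, 1–4 each; standard
  score = raw × 1.25. Banding uses the exact (possibly fractional)
  standard score with closed lower bounds — no rounding before
  banding, so a score can never fall in two bands. SDS bands start at
  53 / 63 / 73. The published SAS cutoffs overlap at 69 ("60–69
  moderate-to-severe; 69 and over severe"); we band severe at ≥ 70, by
  analogy with the SDS band widths. Item totals are treated as already
  keyed; reverse-keyed item handling is out of scope.
* **PHCSS** (self-concept): 60 yes/no items; ≥ 52 = normal. The six
  domain subscores are not used downstream.

## Cohort model and encoding

A cohort is a validated table of one row per participant; every analysis
variable may be missing, and missing cells are kept explicit (no
imputation — downstream stages use pairwise-complete data for
correlations and listwise deletion per model for regressions, which
maximises information in a cohort whose per-variable Ns differ).

The network nodes are the 25 one-hot indicators in a frozen order
(FE1–FE3, ME1–ME3, I1–I4, MS1–MS5, D1–D4, A1–A4, SC, SS). Multi-category
variables expand to one indicator per category; the three dichotomous
variables are single columns with gender female = 1, self-concept
normal = 1 and suicide risk high = 1 (high risk is the modelled event).
A missing source value masks its whole column block. Descriptive rates
are `100·count/denominator` rounded to one decimal; the denominator is
configurable because published cohort tables often mix complete-case and
enrolled denominators — the package never guesses. Age quartiles use
linear interpolation between order statistics.

## Association layer

* **Chi-square**: uncorrected Pearson χ² with 1 df. No Yates or
  Haldane–Anscombe correction by default (the reference values this
  package reproduces match the uncorrected formulas exactly); a 0.5-cell
  correction is available behind a flag for zero cells.
* **Odds ratios**: OR = ad/bc with Wald 95% CI, z = 1.959964. Zero cells
  raise rather than silently correcting.
* **Table reconstruction**: given an exposure margin, candidate totals
  and a printed statistic, every integer table with consistent margins
  (outcome margin searched ± 1) is enumerated; the match must be unique
  within half an ulp of the printed 3-decimal value. When one statistic
  is ambiguous across candidate totals (3-dp odds ratios can collide), a
  second printed statistic can be supplied as a cross-identification
  filter. Ties are an error, never a guess.
* **Logistic regression**: maximum likelihood via IRLS; convergence when
  the score's max absolute value < 1e-8, cap 50 iterations. Multi-
  category covariates enter with a dropped reference category (education:
  primary; income: < 100k; quarrel: never) to avoid the dummy-variable
  trap a full one-hot design would create; age enters in years as a
  continuous covariate. Coefficients diverging past |β| > 15 raise an
  explicit separation error — small cohorts with rare cells (e.g. 4
  divorce cases) do separate, and the pipeline records the affected
  model as unavailable rather than printing unstable estimates.
* **Kendall τ_b**: tie-corrected (C − D)/√((n₀−n₁)(n₀−n₂)) computed from
  the contingency table of unique values (exact, fast for ordinal data),
  with the tie-adjusted normal approximation for p-values. Strength
  labels use bands (0.2, 0.4], (0.4, 0.6], (0.6, 0.8], (0.8, 1.0] on
  |τ| (lower-exclusive).

## Network analysis

Edges come from pairwise-complete Pearson correlations of the indicator
columns. Two views exist on purpose: the untresholded matrix (for
visual export, edge width ω·|r| and a sign/decile colour class) and the
thresholded adjacency `|r| > 0.2` (strict) on which all centralities are
computed. Density is reported for the thresholded graph (the full
correlation graph is complete by construction, so its density is
trivially 1). Centralities treat the thresholded graph as unweighted —
betweenness counts shortest paths, which presumes unweighted edges —
and betweenness is unnormalized, summed over unordered pairs, computed
with Brandes' accumulation; disconnected pairs contribute 0. Rankings
break ties by the frozen node order so exports are stable.

Undefined correlations (a zero-variance column in a subsample) are
masked in the matrix and treated as r = 0 when thresholding, with the
occurrence counted — in bootstrap resamples of a 112-row cohort this
happens routinely when a rare category drops out.

The spring layout implements log attraction along edges (zero force at
the desired distance d₀, pulling together beyond it) plus c/d²
repulsion between all pairs, with update step α decaying geometrically
(0.99) from 0.1, tolerance 1e-4 on the largest node displacement, cap
1000 iterations, and an epsilon jitter (1e-6) for coincident nodes.
Defaults d₀ = 1, k = 1, c = 0.1. The scaling factor ω for edge widths
defaults to 5; both ω and the colour map are conventions, not
statistics.

## Bootstrap stability

B participant-level resamples with replacement at the original n
(default B = 1000); each replicate re-encodes, recomputes pairwise
correlations, thresholds and records per-node degree and betweenness.
Per-replicate values are retained and exportable in long format; the
summary reports per-node means. The (seed, B, θ) triple determines the
result byte-exactly.

## Sample-size recommendation

The "true model" is a random adjacency at a target density whose latent
correlation matrix respects the threshold: edge correlations are drawn
from ±[0.25, 0.6], non-edges from ±[0, 0.15], the matrix is projected to
the nearest PSD correlation matrix, and the construction is verified
(thresholding the latent matrix must recover the adjacency) with bounded
retries. For each candidate n, R datasets are simulated from the latent
correlations — by default dichotomised at each node's median
("binary" node model; a "gaussian" model keeps the continuous scores;
dichotomisation attenuates correlations, so binary designs need larger
n — both are supported because either could plausibly describe
indicator data). Replicates are scored by sensitivity against the true
edge set, g(γ) = (1/R)Σ[γ_r ≥ δ] (boundary inclusive), and the curve is
smoothed by isotonic (pool-adjacent-violators) regression before
choosing the smallest n with g ≥ τ. Common random numbers pair the
candidates: each replicate draws one stream at the largest n and every
candidate uses its leading rows, so the curve is monotone up to genuine
signal, not resampling noise. "Not reached" is a legal outcome. This is
a deliberately transparent grid-search simplification of three-step
power-analysis packages (candidate-range iteration with spline-smoothed
curves and bootstrapped bands); recommendations are qualitative, at the
scale of the grid (default 100–2000 by 100).

## Synthetic-cohort generator

The generator reproduces the *summary structure* of a 112-participant
NSSI-D outpatient cohort: category prevalences per variable
(complete-case denominators), MCAR missingness at the published per-
variable rates, three Kendall τ_b dependence targets
(severe-depression ~ severe-anxiety 0.487, severe-depression ~ low
self-concept 0.248, severe-anxiety ~ father-college 0.327), and the
three exposure × high-risk joint tables recovered by table
reconstruction ((32,13,15,50), (1,13,46,50), (20,10,27,53) at N = 110).

Mechanism: one latent standard-normal coordinate per variable, cut at
the quantiles of its category prevalences. A pairwise target fixes the
latent correlation of its two coordinates through the bivariate-normal
rectangle probability, which is monotone in the correlation — solved by
bisection to 1e-10 (τ targets are first converted to joint-cell
probabilities via the φ identity for binary indicators, with an
explicit feasibility check against the Fréchet bounds). Unconstrained
entries default to 0 and the matrix is completed to PSD by alternating
projections that hold the calibrated entries fixed, so targets survive
the completion exactly whenever a feasible completion exists (it does
for the defaults: the strong depression/self-concept dependence forces
a nonzero anxiety/self-concept latent correlation, which the completion
supplies).

The high-risk flag is the one deliberate departure from the copula. Its
three joint tables over-determine a single latent correlation: the
no-depression band is far more protective (OR 0.084) than any
bivariate-normal discretisation consistent with the severe-band OR 8.205
allows — a one-parameter sweep shows the two odds ratios are never
simultaneously within 15% of their targets. The flag is therefore drawn
from a conditional Bernoulli model
P(high | dep, anx) = σ(α_dep + γ·[anx = severe]), with the mild and
moderate depression bands sharing one baseline, solved by least squares
against the three reconstructed conditional risks plus the overall
high-risk margin (residuals < 5e-3). At n = 100,000 the realized
marginals land within 0.01, the τ targets within 0.03 and all three
odds ratios within 5% of target.

Ages are independent draws on 12–18 with weights chosen once to put the
quartiles near 14 / 15.5 / 17; age is a covariate, not a calibration
surface. MINISM totals, when requested, are drawn uniformly within the
band implied by the risk flag.

What the generator does **not** emulate: dependence among
sociodemographics beyond the three τ targets (all other latent
correlations start at 0), any missingness mechanism beyond MCAR,
item-level response patterns, and longitudinal structure. Passing tests
on synthetic cohorts therefore validate the *computational pipeline* and
its calibration targets — not clinical conclusions about real
adolescents.

## Problem sizes used in the test suite

Tests run the generator at n = 112 (study scale) and n = 100,000
(parameter recovery), the bootstrap at B = 1000 on n = 112 for the
seed-exactness check and B ≤ 300 elsewhere, the sample-size curve on
10-node models with R ≤ 40 and grids up to n = 1000, and the
brute-force betweenness oracle on 200 random graphs of up to 7 nodes.
These sizes were chosen so the full suite completes in well under a
minute while every check retains its statistical meaning.

## Known limitations

* The logistic Model 2/3 fits on 112-row cohorts frequently separate
  (rare covariate cells); the pipeline reports this rather than
  estimating.
* The copula calibration assumes each dependence target involves
  one-sided (extreme-category) indicators, which makes the rectangle
  probability monotone in the latent correlation; targets on middle
  categories of an ordinal variable are not supported.
* The sample-size module's true model is synthetic by construction; its
  recommendations describe networks of that density and effect size,
  not any particular empirical network.
* p-values for τ_b use the normal approximation, which is inaccurate
  below n ≈ 10.
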