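# Methods

This note documents the models, the numerical choices and the limits of
what the package's tests demonstrate.

## The mutual mate-choice model

The theoretical core is a two-class marriage market. A fraction `θ` of men
are rich (rival wealth `m_r`, non-rival wealth `g_r`, both in units of the
poor man's holdings `m_p = g_p = 1`); the rest are poor. A man with `n`
wives has fitness `w(n) = n^δ g^γ ((m − c n)/n)^μ`: the effective number
of wives times their average fitness, with mating investment `c` per wife.
Constraints follow the model's definitions: `μ, γ ∈ (0,1)` with
`μ + γ < 1`, `δ ∈ (μ, 1]`, and `c ≤ m_p` so a poor man can afford one
wife (the worked scenarios sit exactly at `c = m_p`, so the boundary is
admitted).

Two curves determine the equilibrium:

- **Demand.** Maximizing `w(n)` gives the closed form
  `n* = m_r(δ − μ)/(c δ)`. `optimal_wives_numeric` re-derives it by
  bounded scalar maximization of `w` and serves as an independent oracle
  (agreement to 1e-5 is asserted over a 1,000-point random sweep).
- **Supply.** A woman accepts rank `n` with a rich man iff
  `w_r(n)/n ≥ w_p(1)/1`. The rich side is strictly decreasing in `n` for
  `δ ≤ 1`, so the largest acceptable rank is found by bisection
  (`brentq`, tolerance 1e-8) on `(1, m_r/c)`.

The binding side sets the realized wife number; ties (|demand − supply| ≤
1e-9) are classified `market_clearing`. Percent female polygyny in the
demand-limited interior is `P = s θ n*`, truncated at 1 with a `capped`
flag (fixation: all wives have co-wives). An optional integer mode applies
a ceiling to the continuous demand — the convention under which rich men
take whole wives; the continuous closed forms remain the default. Note an
edge of the closed form: at `n* = 1` the formula still counts the wives of
rich men in `P` even though they have no co-wife in the literal sense;
this is the model's reading, kept as is.

The two-class Gini is `G(θ, m_r) = θ m_r/(θ m_r + 1 − θ) − θ` (wealth
share of the rich minus their population share). Its partial derivative in
`θ` is `m_r/(1 + θ(m_r − 1))² − 1`, negative exactly when
`θ > 1/(1 + √m_r)`; the sign condition is tested against a
central-difference derivative (h = 1e-6). Over that range a growing poor
class raises the Gini while mechanically lowering `P` — the package's
central comparative static.

## Empirical statistics

The Gini is half the relative mean absolute difference, computed with the
sorted O(n log n) identity and verified against the O(n²) brute force; no
small-sample correction is applied. `proportion_rich_share` uses the
minimal-k rule on a descending stable sort (ties resolve by input order),
so equal-wealth populations get a deterministic, convention-dependent
answer — the convention is documented rather than hidden. The two-class
reduction reports the ratio of class *means* (medians would be an
alternative; means are used throughout and the choice is exposed for
sensitivity analysis). "Wives" always means *times married*: sequential
marriage counts as polygyny because each wife's offspring are rival
claimants on the father's wealth.

## Synthetic data generator

Each site draws completed (age-60) quantities first, then censors them:

- **Wealth**: two-class `{θ, m_r}` or log-normal `{meanlog, sdlog}`. The
  archetype defaults are horticultural θ=0.45, m_r=5; agricultural
  θ=0.05, m_r=35; agropastoral θ=0.2, m_r=8; forager log-normal
  sdlog=0.5 — the stylized contrast between many-moderately-rich and
  few-very-rich economies, with forager inequality low and continuous.
- **Wives**: Poisson around the demand rule `n* = (w/ref)(δ − μ)/(c δ)`
  (ref = the poor-class level: 1 for two-class wealth, the lower quartile
  for log-normal), truncated at 10. Poisson rounding keeps the monotone
  wealth→wives link while integer-valued. Elasticity defaults are
  μ = 0.08 (the order of magnitude empirical studies report), δ = 0.5,
  c = 1.
- **Reproductive success**: negative binomial (shape 10 by default;
  Poisson as the limit) with mean `base · n^(δ−μ) · (w/ref)^μ` for married
  men, zero for never-married men. Generator and fitter share this family
  deliberately; robustness is probed by mismatching them in tests.
- **Censoring**: ages uniform on 18–80 by default; the acquisition clock
  is a gamma-CDF in years since 18 (shape 3, scale 8), saturating at 60.
  Observed wealth is the completed value times the curve (deterministic);
  observed wives and reproductive success are binomial thinnings, so
  observed ≤ completed always holds. Latent `true_completed_*` columns
  are retained for exact scoring of every downstream estimator.

What the generator does *not* emulate: female-side records, divorce
timing, mortality/survivorship, household composition, covariation of
elasticities with subsistence, or any specific real population's values.
Passing tests therefore show that the estimators recover the generative
process they assume, and that directional contrasts follow from the wealth
structure — not that any real dataset would yield the same numbers.

## Age adjustment (completed measures)

Post-censor acquisition is a positive random variable. Per population and
measure, a 3-parameter scaled gamma-CDF `m(a) = K·F(a − 18; shape, scale)`
is fitted to the cross-section (log-normal likelihood for wealth on
positive values; negative binomial for wife counts, zeros included), with
weakly informative normal priors on the log scale. Fitting requires ≥ 20
men spanning ≥ 3 age decades. A man censored at `a < 60` receives a gamma
increment with mean `(m(60) − m(a))` times his relative position
`obs/m(a)` clipped to `[0.1, 10]` (increment shape 4); men at or past 60
are left untouched. Wife counts are completed continuously and rounded
stochastically. Population summaries (Gini, wealth ratio and proportion
rich at φ = 0.5, percent polygyny) are propagated through the joint draws
and reported as medians with 90% intervals, 1,000 draws by default.

This increment model is the package's own construction: a concrete,
defensible positive-increment imputation, *not* a reproduction of any
particular study's unpublished specification. Per-population values from
published comparative tables are consequently not targets; the packaged
table of published medians is used only for in-table arithmetic
(block means, correlations).

## Elasticity regression

For married men, `rs ~ NegBinomial(mean = exp(α_j + b_j log n + μ_j log w̃))`
with `b = δ − μ` and `w̃` wealth scaled by the population mean (zero
wealth shifted by 1% of the mean before logging; the shift is a config
sensitivity flag). Site coefficients are partially pooled through normal
distributions with hyperpriors `A ~ N(1, 5²)`, `B, M ~ N(0, 1)`,
`log σ ~ N(log 0.3, 1²)`, `log φ ~ N(log 10, 1.5²)` — weakly informative,
with no hard constraint to `μ ∈ (0,1)` or `δ > μ`: the theory's
assumptions are checked against the posterior, not imposed. Populations
whose married men all share one wife count are kept for `μ` but flagged
inestimable for `δ − μ`, and `δ` is not reported there.

Posteriors are approximated by MAP (L-BFGS with an analytic gradient,
ftol 1e-12) plus a Laplace expansion: the Hessian is formed by central
differences of the gradient, eigenvalue-floored, and draws are taken from
the Gaussian at the mode. This is a deliberate design for speed and
determinism at simulation scale; its accuracy is validated by simulation
(20-replicate studies at 10 sites × 300 men give 90%-interval coverage in
the 0.75–0.90 range for the global means) and by agreement with an
independent single-population negative-binomial GLM. For strongly skewed
or multimodal posteriors a full MCMC would be preferable; that regime is
outside the package's validated envelope.

Problem sizes in the shipped tests (10 sites × 300 men × 20 replicates;
20 sites × 200 men for the completed-polygyny tracking check) were chosen
as the smallest designs at which the recovery properties stabilize.

## Known limitations

- The analytic model is two-class with identical females; continuous
  wealth enters only through the empirical reductions.
- Non-rival wealth `γ` is not estimable from rival-wealth proxies; a
  simulated non-rival confound measurably inflates `μ` (this caveat has
  its own test).
- The Laplace posterior can understate tail mass; intervals are
  calibrated by simulation, not exact.
- Age adjustment assumes monotone acquisition with no mortality selection
  and no left truncation.
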