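# Methods

## Model and assumptions

The package analyses balanced randomized-complete-block trials: `g`
families × `r` replicate blocks × one or two conditions × `T` traits, one
observation per cell.  The per-condition linear model is the additive
two-way decomposition without interaction,

    y_fr = μ + ρ_r + γ_f + ε_fr,

with blocks `ρ`, family (genotypic) effects `γ` and i.i.d. residuals `ε`.
Because the design is balanced, sums of squares have closed forms and are
computed by direct summation; the test suite cross-checks the
decomposition against a general linear-model fit (statsmodels
`anova_lm`).  `F` statistics test each effect against the residual mean
square, with significance flagged at 5% (`a`) and 1% (`b`).

All genetic parameters are on the **family-mean basis**:
`σ²_g = (MSf − MSe)/r`, `σ²_e = MSe/r`, `σ²_p = σ²_g + σ²_e = MSf/r`, and
`h²_b = σ²_g/σ²_p = 1 − MSe/MSf`.  This is broad-sense heritability: the
family effect aggregates all genetic variance among family means, with no
additive/dominance split.  A negative raw `h²_b` (families varying less
than the error expectation) is clamped to 0 for reporting and for the
expected genetic advance, but the raw value is kept because the
heritability-stability ratio needs its sign (below).

Expected genetic advance uses `EGA = k·h²_b·√σ²_p` with `σ²_p` on the
family-mean basis, and `EGA% = 100·EGA/mean`.  The default selection
intensity `k = 2.063` corresponds to 5% truncation of a normal trait and
is configurable; since EGA depends on unpublished grand means, the bundled
case tables are used to check its *eigenvector* (scale-free) behaviour
only, not absolute EGA values.

Genetic covariance uses the analysis-of-covariance mean cross products,
`cov_g = (MCPf − MCPe)/r`, and `r_g = cov_g/√(σ²_g(X)·σ²_g(Y))`.  `r_g`
is undefined when either raw genetic variance is zero; when the product of
raw variances is negative (possible with negative variance estimates) the
denominator uses its magnitude, so the reported sign comes from the
covariance alone.  Estimated `|r_g|` may exceed 1; the uncapped value
feeds the weighting stage, a copy clipped to [−1, 1] is reported.

## Stability statistics

- **SI** is the absolute OLS slope (ordinary regression with intercept,
  via `scipy.stats.linregress`) of stress-condition family means on
  normal-condition family means.  Family means — not raw plot values — are
  used, matching the family-level focus of the whole analysis.  Under this
  definition a slope near 0 (stress expression unrelated to normal
  expression) counts as *stable*; this differs from the classical
  joint-regression convention for genotypes, where slope 1 is average
  stability, and is applied exactly as defined.
- **SIBH** is `|h²_b(stress)/h²_b(normal)|` computed from the *unclamped*
  heritabilities.  The sign-carrying ratio matters: a trait with slightly
  negative normal-condition `h²_raw` and small positive stress `h²_raw`
  must yield a small SIBH magnitude, which only the raw ratio produces
  (the bundled fruit-weight row, 0.094, is the canonical check).  SIBH is
  undefined when the normal-condition raw heritability is exactly 0; the
  pipeline then keeps the trait but sets its SIBH contribution to 0 and
  logs the decision.

## Eigenvector weighting

Comparison matrices are derived from measured values, `A_ij = v_i/v_j`,
hence exactly reciprocal, rank one and consistent: the principal
eigenvalue is `N` and the principal eigenvector is proportional to `v`.
The implementation therefore uses the direct path — eigenvalue `N`,
eigenvector `v/‖v‖₂`, sign oriented along `v` — and the tests verify
equivalence with a dense eigensolver to 1e-9 up to N = 20.  Consistency-
ratio checking of classical expert-judgment AHP is vacuous here (matrices
are consistent by construction) and is not implemented.

Normalization is **unit Euclidean norm**, not the classical sum-to-one of
AHP: the L2 convention is what reproduces the bundled case study's
eigenvector columns from its parameter values, and it keeps negative
entries (correlation columns) meaningful.  Negative parameter values pass
through unchanged, so eigen entries and final weights can be negative.

The final trait weight is the plain, unweighted row sum of the
per-parameter eigenvector entries (verified against all 15 published
final weights).  Family scores are the weighted sum of per-trait
unit-norm eigenvectors over condition-averaged family means; selection
takes the top `count` (or `ceil(fraction·n)`) with stable input-order tie
break.

Direction handling ("low is good"): values are reflected as
`max(v) − v_i` before normalization.  For a fresh analysis the SI
parameter column is treated as lower-better, per the statistic's
interpretation.  In `reproduction_mode` the SI column is left
untransformed, because the bundled published weight table is consistent
only with the untransformed normalized SI column; both behaviours are
explicit configuration.  An optional z-score pre-standardization exists
but is off by default — the unit-norm step already removes scale, and
there is no evidence the case study centred its columns.

## Trait filtering

A trait is excluded iff its family effect is non-significant (default
threshold 0.05) in *both* conditions, or its clamped heritability is 0 in
both — the permissive OR reading of "no usable genetic signal anywhere".
Every exclusion is logged with its reason, and retained + excluded
partition the input trait list.

## Synthetic trials

The generator draws family genetic effects from a multivariate normal
with per-trait variance `σ²_g` and a user-supplied PSD genetic
correlation matrix; block effects and plot residuals are independent
Gaussians (block variance is per-trait, since trait scales differ by
orders of magnitude).  Stress-condition family effects are
`a_t·g + noise`, which *defines* trait stability in the generator: the SI
regression has slope truth `|a_t|`, and stress genetic variance is
`a²σ²_g + σ²_noise`, giving closed-form truths for h², SIBH and r_g in
both conditions.

What the generator does not emulate: non-Gaussian traits, block×family
interaction, spatial field trends, genotype×environment structure beyond
the per-trait linear response, measurement censoring.  Passing recovery
tests therefore show the estimators are correct *under the model they
assume*, not that real trials satisfy those assumptions.

A note on SI recovery: the regressor (normal-condition family mean)
carries error variance `σ²_e/r`, so the OLS slope estimates the
attenuated quantity `a·σ²_g/(σ²_g + σ²_e/r)`.  The recovery suites use
specs whose attenuation is well inside the stated tolerance (e.g.
`σ²_g = 4, σ²_e = 0.3, r = 3` ⇒ factor 0.976); with noisy regressors the
bias against `|a|` grows accordingly.

`case_study_spec()` emulates the bundled tomato study: 57 families × 3
blocks × 15 traits, variance components taken from the published mean
squares (negative genetic variances clipped at 0, e.g. normal-condition
fruit weight), stress slopes from the published SI column, block
variances backed out of the replication mean squares, and a genetic
correlation matrix embedding the published (capped) correlations with the
two breeding targets, repaired to the nearest PSD matrix by eigenvalue
clipping.  Grand means are unpublished; plausible tomato values are fixed
once in the package and only anchor the simulated scale.  The stress mean
shift is 0 because no estimator in the package depends on it.

## Numerical choices and problem sizes

- Golden tests against the bundled printed tables propagate the tables'
  own 3-d.p. rounding: a mean square is known to ±0.0005, so the implied
  heritability interval — not a fictitious exact value — is asserted; a
  row sum of eight printed entries is checked to ±0.0045 (8 × half-ulp).
  For well-scaled traits these intervals collapse to 3-d.p. equality.
- `SS(error)` is obtained by subtraction and clipped at 0 against
  floating-point cancellation; `F` with a zero error mean square is `inf`
  (p = 0) when the effect varies and NaN when nothing varies.
- Self-correlation `r_g(X, X)` is set to exactly 1, not computed.
- Ties in selection break by input order (stable sort), documented and
  deterministic; reruns with identical input and configuration produce
  byte-identical CSVs.
- Monte-Carlo recovery suites use 200 replicates at g = 100, r = 3 for
  h²/SI/SIBH and 100 replicates at g = 200 for r_g, sizes at which the
  Monte-Carlo standard errors are a small fraction of the assertion
  tolerances (±0.03, ±0.05, ±0.05, ±0.1 respectively).
- All randomness flows through a single integer seed per spec;
  multi-replicate harnesses spawn child seeds below 2³¹ from one
  generator and never touch global state.

## Known limitations

- Estimators assume an exactly balanced design; missing plots are a hard
  validation error, not imputed.
- Broad-sense heritability only; no REML/mixed models, no narrow-sense or
  dominance decomposition.
- Published SI, genetic-correlation and absolute family-score values from
  the case study are not recomputable without its raw plot data (and, for
  the correlation eigenvector columns, without its unstated capping
  convention); those are validated structurally and by parameter recovery
  instead of golden values.
- Stability statistics are defined for traits across exactly one
  normal/stress pair, not for genotypes across many environments.
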